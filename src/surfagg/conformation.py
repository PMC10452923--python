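"""Per-peptide conformational classification.

Distance RMSD (DRMSD) measures similarity to a reference conformation as
the root-mean-square difference over all intramolecular Cα-Cα pair
distances:

    DRMSD = sqrt( (1/N) * sum_i (r_i - r_i_ref)^2 ),   N = R(R-1)/2

It needs no superposition and is invariant to rigid motions and reflection
(mirror images are indistinguishable — a metric property, not corrected).
Values are reported in Å, the conventional axis unit, though coordinates are
handled in nm.  Backbone (φ, ψ) dihedral densities complete the picture:
β-strand conformations populate the upper-left Ramachandran quadrant,
α-helical ones the lower-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from .core import DEFAULT_WINDOW_PS, Frame, MolecularSystem, Trajectory

NM_TO_ANGSTROM = 10.0

DEFAULT_DRMSD_BIN_A = 0.1   # Å
DEFAULT_RAMA_BIN_DEG = 5.0

QUADRANTS = ("upper_left", "upper_right", "lower_left", "lower_right")


@dataclass
class ReferenceDistances:
    """All intramolecular Cα-Cα distances of a reference conformation (nm).

    Pair ordering is lexicographic over residue-position pairs (p, q), p < q
    — the ordering scipy's ``pdist`` produces — so vectors from different
    sources are comparable.
    """

    label: str
    distances: np.ndarray  # nm, length R(R-1)/2
    n_residues: int

    @property
    def n_pairs(self) -> int:
        return self.n_residues * (self.n_residues - 1) // 2

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.distances) != self.n_pairs:
            raise ValueError(
                f"reference {self.label!r}: expected {self.n_pairs} pair "
                f"distances for R={self.n_residues}, got {len(self.distances)}")
        if np.any(self.distances <= 0):
            raise ValueError(f"reference {self.label!r} has non-positive distances")


def reference_from_coordinates(ca_coords: np.ndarray, label: str) -> ReferenceDistances:
    """Build a reference distance vector from Cα coordinates (nm)."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 3:
        raise ValueError("need at least three Cα coordinate triples")
    d = pdist(ca)
    if np.any(d == 0):
        raise ValueError("duplicate Cα coordinates in reference")
    return ReferenceDistances(label=label, distances=d, n_residues=ca.shape[0])


def load_reference(path: str, label: str) -> ReferenceDistances:
    """Load a reference from a PDB file (Cα extracted) or a plain-text
    distance vector (one-line header, then one distance in nm per line)."""
    if path.lower().endswith((".pdb", ".gro")):
        from .io import load_system
        system = load_system(path)
        ca = system.calpha_of_peptide(0)
        import MDAnalysis as mda
        u = mda.Universe(path)
        coords = u.atoms.positions[getattr(system, "_atom_indices")][ca] / 10.0
        return reference_from_coordinates(coords, label)
    values = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if line:
                values.append(float(line))
    n = len(values)
    r = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
    return ReferenceDistances(label=label, distances=np.array(values), n_residues=r)


def drmsd(ca_coords: np.ndarray, ref: ReferenceDistances) -> float:
    """DRMSD (Å) of a Cα conformation against a reference distance vector."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.shape[0] != ref.n_residues:
        raise ValueError(
            f"conformation has {ca.shape[0]} residues, reference "
            f"{ref.label!r} has {ref.n_residues}")
    diff = pdist(ca) - ref.distances
    return float(np.sqrt(np.mean(diff * diff)) * NM_TO_ANGSTROM)


@dataclass
class DRMSDSeries:
    """Per-frame, per-peptide DRMSD values (Å) and their window histogram."""

    reference: str
    times: np.ndarray                 # (n_frames,)
    values: np.ndarray                # (n_frames, n_peptides), Å
    bin_width: float                  # Å
    bin_edges: np.ndarray = field(default=None)
    histogram: np.ndarray = field(default=None)  # probability mass per bin

    def mass_below(self, threshold_a: float) -> float:
        """Fraction of (frame, peptide) samples with DRMSD below threshold."""
        return float(np.mean(self.values < threshold_a))

    @property
    def peak_position(self) -> float:
        i = int(np.argmax(self.histogram))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


def peptide_drmsd_frame(frame: Frame, system: MolecularSystem,
                        ref: ReferenceDistances) -> np.ndarray:
    out = np.empty(system.n_peptides)
    for p in range(system.n_peptides):
        out[p] = drmsd(frame.coords[system.calpha_of_peptide(p)], ref)
    return out


def drmsd_histograms(traj: Trajectory, refs: Sequence[ReferenceDistances],
                     window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                     bin_width_a: float = DEFAULT_DRMSD_BIN_A,
                     peptides: Optional[Sequence[int]] = None,
                     allow_short: bool = False) -> Dict[str, DRMSDSeries]:
    """Pooled per-peptide DRMSD histograms over the trailing window.

    ``peptides`` restricts pooling (e.g. to surface-contact peptides only);
    the per-peptide series is retained on the result for later splits.
    """
    if not refs:
        raise ValueError("at least one reference is required")
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    sel = list(range(traj.system.n_peptides)) if peptides is None else list(peptides)
    out = {}
    for ref in refs:
        vals = np.array([peptide_drmsd_frame(fr, traj.system, ref)[sel]
                         for fr in frames])
        hi = max(vals.max() + bin_width_a, 10 * bin_width_a)
        edges = np.arange(0.0, hi + bin_width_a, bin_width_a)
        hist, edges = np.histogram(vals.ravel(), bins=edges)
        hist = hist / hist.sum()
        out[ref.label] = DRMSDSeries(
            reference=ref.label, times=np.array([fr.time for fr in frames]),
            values=vals, bin_width=bin_width_a, bin_edges=edges, histogram=hist)
    return out


# -- backbone dihedrals -------------------------------------------------------

def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def backbone_dihedrals(frame: Frame, system: MolecularSystem,
                       peptide: int) -> List[Tuple[int, float, float]]:
    """(residue position, φ, ψ) for interior residues of one peptide.

    φ is defined for residues 2..R (needs the previous C), ψ for 1..R-1
    (needs the next N); only residues with both are returned.
    """
    R = system.residues_per_peptide
    atoms_of = system.residue_atoms[peptide]

    def atom(r, name):
        a = atoms_of[r][system.names[atoms_of[r]] == name]
        if len(a) == 0:
            raise ValueError(
                f"missing backbone atom {name} in residue {r} of peptide {peptide}")
        return frame.coords[a[0]]

    out = []
    for r in range(2, R):
        phi = torsion_angle(atom(r - 1, "C"), atom(r, "N"), atom(r, "CA"), atom(r, "C"))
        psi = torsion_angle(atom(r, "N"), atom(r, "CA"), atom(r, "C"), atom(r + 1, "N"))
        out.append((r, phi, psi))
    return out


@dataclass
class RamachandranDensity:
    """2D (φ, ψ) histogram over (-180, 180]², normalised to unit mass."""

    density: np.ndarray
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    bin_deg: float
    quadrant_occupancy: Dict[str, float]
    samples: np.ndarray  # (n, 2) raw (φ, ψ) pairs


def quadrant_of(phi: float, psi: float) -> str:
    if phi < 0:
        return "upper_left" if psi > 0 else "lower_left"
    return "upper_right" if psi > 0 else "lower_right"


def ramachandran(traj: Trajectory, window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                 bin_deg: float = DEFAULT_RAMA_BIN_DEG,
                 allow_short: bool = False) -> RamachandranDensity:
    """Interior-residue (φ, ψ) density pooled over peptides and window frames."""
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    samples = []
    for fr in frames:
        for p in range(traj.system.n_peptides):
            for (_, phi, psi) in backbone_dihedrals(fr, traj.system, p):
                samples.append((phi, psi))
    samples = np.array(samples)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    h, pe, se = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges, edges))
    h = h / h.sum()
    occ = {q: 0.0 for q in QUADRANTS}
    for phi, psi in samples:
        occ[quadrant_of(phi, psi)] += 1.0
    for q in occ:
        occ[q] /= len(samples)
    return RamachandranDensity(density=h, phi_edges=pe, psi_edges=se,
                               bin_deg=bin_deg, quadrant_occupancy=occ,
                               samples=samples)
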