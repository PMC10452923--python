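"""Core data model: molecular systems, frames, trajectories, periodic boxes.

All internal lengths are nanometres; times are picoseconds; masses are amu.
The 4 Å heavy-atom contact cutoff used throughout is stored as 0.4 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: Default heavy-atom contact cutoff (nm): two peptides belong to the same
#: oligomer when any pair of non-hydrogen atoms is strictly closer than this.
CONTACT_CUTOFF_NM = 0.4

#: Default trailing analysis window (ps) = 100 ns.
DEFAULT_WINDOW_PS = 100_000.0

ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "AU": 196.967, "NA": 22.990, "CL": 35.45,
    "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38, "FE": 55.845,
}

#: Residue one/three-letter naming for the KLVFFAE fragment.
KLVFFAE_RESNAMES = ("LYS", "LEU", "VAL", "PHE", "PHE", "ALA", "GLU")
KLVFFAE_LABELS = ("K16", "L17", "V18", "F19", "F20", "A21", "E22")


def mass_of_element(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)


def is_heavy(element: str) -> bool:
    """Heavy atom = anything other than hydrogen (or deuterium)."""
    return element.upper() not in ("H", "D")


@dataclass
class Box:
    """Orthorhombic box: edge lengths (nm) and per-axis periodicity flags.

    Surface systems are periodic in x and y only; bulk-solution systems are
    periodic in all three axes.
    """

    lengths: np.ndarray
    periodic: np.ndarray

    def __init__(self, lengths: Sequence[float], periodic: Sequence[bool] = (True, True, True)):
        self.lengths = np.asarray(lengths, dtype=float)
        self.periodic = np.asarray(periodic, dtype=bool)
        if self.lengths.shape != (3,) or self.periodic.shape != (3,):
            raise ValueError("box requires three edge lengths and three periodicity flags")
        if np.any(self.lengths <= 0):
            raise ValueError(f"box edges must be strictly positive, got {self.lengths}")

    @classmethod
    def solution(cls, lengths: Sequence[float]) -> "Box":
        return cls(lengths, (True, True, True))

    @classmethod
    def surface(cls, lengths: Sequence[float]) -> "Box":
        return cls(lengths, (True, True, False))


def minimum_image_shift(disp: np.ndarray, box: Box) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Axes flagged non-periodic are left untouched.  ``disp`` may be any
    (..., 3) array.
    """
    disp = np.asarray(disp, dtype=float)
    out = disp.copy()
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            out[..., ax] -= L * np.round(out[..., ax] / L)
    return out


def minimum_image_distance(a: Sequence[float], b: Sequence[float], box: Box) -> float:
    """Smallest |a - b| over periodic images in the periodic axes (nm)."""
    d = minimum_image_shift(np.asarray(a, float) - np.asarray(b, float), box)
    return float(np.linalg.norm(d))


def pairwise_min_image_distances(xa: np.ndarray, xb: np.ndarray, box: Box) -> np.ndarray:
    """All-pairs minimum-image distance matrix between two coordinate sets."""
    disp = xa[:, None, :] - xb[None, :, :]
    disp = minimum_image_shift(disp, box)
    return np.sqrt(np.sum(disp * disp, axis=-1))


@dataclass
class SurfaceModel:
    """Geometry of an fcc(111) slab (the Au(111) surface model).

    lattice_a is the cubic lattice parameter in Å (4.14 Å for gold); the
    in-plane nearest-neighbour spacing is a/sqrt(2).  top_z is the z
    coordinate (nm) of the topmost atomic layer, detected from coordinates.
    """

    lattice_a: float = 4.14
    nx: int = 20
    ny: int = 12
    layers: int = 5
    top_z: float = 0.0
    lx: float = 0.0
    ly: float = 0.0
    atom_positions: Optional[np.ndarray] = None  # (n, 3) nm, slab atoms

    #: tolerance band (nm) for assigning atoms to the top layer: 0.5 Å
    LAYER_TOL_NM = 0.05

    @classmethod
    def from_positions(cls, positions: np.ndarray, lattice_a: float = 4.14,
                       nx: int = 0, ny: int = 0, layers: int = 0) -> "SurfaceModel":
        """Detect the top layer from slab-atom coordinates (max-z band)."""
        positions = np.asarray(positions, float)
        if positions.size == 0:
            raise ValueError("cannot build a SurfaceModel from zero slab atoms")
        zmax = positions[:, 2].max()
        top = positions[positions[:, 2] >= zmax - cls.LAYER_TOL_NM]
        lx = positions[:, 0].max() - positions[:, 0].min()
        ly = positions[:, 1].max() - positions[:, 1].min()
        return cls(lattice_a=lattice_a, nx=nx, ny=ny, layers=layers,
                   top_z=float(top[:, 2].mean()), lx=float(lx), ly=float(ly),
                   atom_positions=positions)


class MolecularSystem:
    """Atoms grouped into residues grouped into peptides, plus optional slab.

    All peptides must share the same residue sequence and per-atom layout
    (homo-oligomer assumption).  Gold atoms live in ``surface``, never in the
    peptide atom table.
    """

    def __init__(self, names, elements, residue_pos, resnames, peptide_index,
                 chain_tags=None, masses=None, surface: Optional[SurfaceModel] = None):
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_pos = np.asarray(residue_pos, dtype=int)
        self.resnames = np.asarray(resnames, dtype=object)
        self.peptide_index = np.asarray(peptide_index, dtype=int)
        n = len(self.names)
        if chain_tags is None:
            chain_tags = [chr(ord("A") + (i % 26)) for i in self.peptide_index]
        self.chain_tags = np.asarray(chain_tags, dtype=object)
        if masses is None:
            masses = [mass_of_element(e) for e in self.elements]
        self.masses = np.asarray(masses, dtype=float)
        self.heavy = np.array([is_heavy(e) for e in self.elements], dtype=bool)
        for arr in (self.elements, self.residue_pos, self.resnames,
                    self.peptide_index, self.chain_tags, self.masses):
            if len(arr) != n:
                raise ValueError("atom attribute arrays must share one length")
        self.surface = surface
        self._validate()
        self._build_indexes()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if self.n_atoms == 0:
            raise ValueError("system contains no peptide atoms")
        pep_ids = np.unique(self.peptide_index)
        if not np.array_equal(pep_ids, np.arange(len(pep_ids))):
            raise ValueError("peptide indices must be contiguous from 0")
        ref_sig = None
        for p in pep_ids:
            sel = self.peptide_index == p
            sig = (tuple(self.residue_pos[sel]), tuple(self.resnames[sel]),
                   tuple(self.names[sel]))
            n_res = len(np.unique(self.residue_pos[sel]))
            if ref_sig is None:
                ref_sig, ref_nres = sig, n_res
            elif sig != ref_sig:
                tag = self.chain_tags[sel][0]
                raise ValueError(
                    f"peptide {p} (chain {tag!r}) has {n_res} residues / a different "
                    f"atom layout than peptide 0 ({ref_nres} residues); all peptide "
                    "copies must be identical")

    def _build_indexes(self) -> None:
        nmol = self.n_peptides
        self.peptide_atoms = [np.flatnonzero(self.peptide_index == p) for p in range(nmol)]
        self.peptide_heavy = [idx[self.heavy[idx]] for idx in self.peptide_atoms]
        self.residue_atoms = []
        for p in range(nmol):
            idx = self.peptide_atoms[p]
            self.residue_atoms.append(
                {r: idx[self.residue_pos[idx] == r]
                 for r in np.unique(self.residue_pos[idx])})
        self.calpha = np.flatnonzero(self.names == "CA")

    # -- basic queries --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_peptides(self) -> int:
        return int(self.peptide_index.max()) + 1 if self.n_atoms else 0

    @property
    def residues_per_peptide(self) -> int:
        return len(np.unique(self.residue_pos[self.peptide_atoms[0]]))

    def calpha_of_peptide(self, p: int) -> np.ndarray:
        idx = self.peptide_atoms[p]
        ca = idx[self.names[idx] == "CA"]
        order = np.argsort(self.residue_pos[ca])
        return ca[order]

    def residue_labels(self) -> list:
        """Residue labels in the K16..E22 style when the peptide is KLVFFAE."""
        idx = self.peptide_atoms[0]
        rpos = sorted(np.unique(self.residue_pos[idx]))
        seq = []
        for r in rpos:
            seq.append(str(self.resnames[self.residue_atoms[0][r][0]]))
        if tuple(seq) == KLVFFAE_RESNAMES:
            return list(KLVFFAE_LABELS)
        one = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
               "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
               "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
               "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}
        return [f"{one.get(nm, 'X')}{r}" for nm, r in zip(seq, rpos)]


@dataclass
class Frame:
    """One time point: coordinates (nm) for every peptide atom, plus the box."""

    time: float  # ps
    coords: np.ndarray  # (n_atoms, 3) nm
    box: Box

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")


class Trajectory:
    """A MolecularSystem bound to a time-ordered sequence of Frames."""

    def __init__(self, system: MolecularSystem, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("no frames: a trajectory must contain at least one frame")
        for fr in frames:
            if fr.coords.shape[0] != system.n_atoms:
                raise ValueError(
                    f"frame at t={fr.time} ps has {fr.coords.shape[0]} atoms, "
                    f"system has {system.n_atoms}")
        times = np.array([fr.time for fr in frames])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError(f"frame times must be strictly increasing, got {times}")
        self.system = system
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def stride_ps(self) -> float:
        t = self.times
        return float(t[1] - t[0]) if len(t) > 1 else 0.0

    def window_frames(self, window_ps: Optional[float], allow_short: bool = False) -> list:
        """Frames in the trailing window of the stated duration.

        The analysis convention is a trailing 100 ns window; trajectories
        shorter than the window raise unless ``allow_short`` requests the
        trailing-20% fallback.
        """
        if window_ps is None:
            return list(self.frames)
        t = self.times
        span = t[-1] - t[0]
        if span < window_ps and len(self.frames) > 1:
            if not allow_short:
                raise ValueError(
                    f"trajectory spans {span} ps, shorter than the {window_ps} ps "
                    "window; pass an explicit shorter window or allow_short=True")
            window_ps = 0.2 * span
        t0 = t[-1] - window_ps
        return [fr for fr in self.frames if fr.time >= t0 - 1e-9]
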