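"""Constructive synthetic systems with planted ground truth.

Everything the analysis pipeline measures can be planted here exactly:
oligomer partitions (clusters chained at ~3 Å heavy-atom separations,
well-separated otherwise), backbone conformations (ideal β-strand,
flat-lying surface-bent, or coil dihedral sets), adsorption states above an
fcc(111) slab, and frame-indexed changes of aggregation state.  Peptides are
built at backbone-plus-pseudo-side-chain resolution (N, H, Cα, C, O plus one
side-chain pseudo-atom per residue): enough for heavy-atom contacts, Cα
distance metrics, φ/ψ dihedrals and amide hydrogen-bond geometry while
keeping fixtures tiny.

With zero noise the constructive path is deterministic; all randomness
(coil dihedrals, coordinate noise) flows from the single seed in the spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (Box, Frame, MolecularSystem, SurfaceModel, Trajectory,
                   KLVFFAE_RESNAMES)
from .clustering import partition_frame, min_heavy_distance
from .conformation import ReferenceDistances, reference_from_coordinates
from .surface import build_slab

# ideal backbone geometry (nm / degrees)
B_N_CA, B_CA_C, B_C_N = 0.1458, 0.1525, 0.1329
B_C_O, B_N_H, B_CA_CB = 0.1231, 0.101, 0.153
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA = 111.0, 116.6, 121.7
ANG_CA_C_O, ANG_C_CA_CB = 120.5, 110.1
OMEGA = 180.0

#: planted dihedral sets
BETA_PHI_PSI = (-139.0, 135.0)      # ideal antiparallel β-strand
BENT_PHI_PSI = (-60.0, -60.0)       # flat-lying surface-bent stand-in

RESIDUE_ATOMS = ("N", "H", "CA", "C", "O", "CB")
RESIDUE_ELEMENTS = ("N", "H", "C", "C", "O", "C")
ATOMS_PER_RESIDUE = len(RESIDUE_ATOMS)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) and
    torsion(A,B,C,D) as stated."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(angle),
                               np.sin(angle) * np.cos(torsion),
                               np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: Sequence[float], psis: Sequence[float]) -> Dict[str, np.ndarray]:
    """Backbone + O/H/CB coordinates for R residues from dihedral lists.

    ``phis[i]`` is used for residue i (ignored for i = 0), ``psis[i]`` for
    residue i (the final one orients only that residue's carbonyl).
    """
    R = len(phis)
    N = np.zeros((R, 3))
    CA = np.zeros((R, 3))
    C = np.zeros((R, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANG_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, R):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, ANG_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, ANG_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, ANG_N_CA_C, phis[i])
    O = np.zeros((R, 3))
    H = np.zeros((R, 3))
    CB = np.zeros((R, 3))
    for i in range(R):
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, ANG_CA_C_O, psis[i] + 180.0)
        CB[i] = place_atom(N[i], C[i], CA[i], B_CA_CB, ANG_C_CA_CB, -122.6)
        if i == 0:
            H[i] = place_atom(C[i], CA[i], N[i], B_N_H, 118.0, 180.0)
        else:
            u1 = (C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
            u2 = (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
            d = -(u1 + u2)
            H[i] = N[i] + B_N_H * d / np.linalg.norm(d)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H, "CB": CB}


def _assemble(parts: Dict[str, np.ndarray]) -> np.ndarray:
    R = parts["N"].shape[0]
    coords = np.empty((R * ATOMS_PER_RESIDUE, 3))
    for r in range(R):
        for k, name in enumerate(RESIDUE_ATOMS):
            coords[r * ATOMS_PER_RESIDUE + k] = parts[name][r]
    return coords


def _calpha_rows(R: int) -> np.ndarray:
    return np.arange(R) * ATOMS_PER_RESIDUE + RESIDUE_ATOMS.index("CA")


def _phe_cb_rows(resnames: Sequence[str]) -> np.ndarray:
    rows = [i * ATOMS_PER_RESIDUE + RESIDUE_ATOMS.index("CB")
            for i, rn in enumerate(resnames) if rn == "PHE"]
    return np.array(rows, dtype=int)


def _orient(coords: np.ndarray, resnames: Sequence[str], flat: bool) -> np.ndarray:
    """Deterministic rigid orientation.

    flat: both Phe side-chain pseudo-atoms end on the z=0 plane with the rest
    of the molecule above, Phe-Phe axis along y.  Otherwise: first->last Cα
    axis along y.
    """
    R = len(resnames)
    ca = coords[_calpha_rows(R)]
    com = coords.mean(axis=0)
    if flat:
        f = coords[_phe_cb_rows(resnames)]
        if len(f) < 2:
            raise ValueError("flat orientation needs two Phe residues")
        mid = 0.5 * (f[0] + f[1])
        e_long = f[1] - f[0]
        e_long /= np.linalg.norm(e_long)
        v = com - mid
        v_perp = v - np.dot(v, e_long) * e_long
        e_z = v_perp / np.linalg.norm(v_perp)
        origin = mid
    else:
        e_long = ca[-1] - ca[0]
        e_long /= np.linalg.norm(e_long)
        w = coords[1] - coords[0]
        v_perp = w - np.dot(w, e_long) * e_long
        e_z = v_perp / np.linalg.norm(v_perp)
        origin = com
    e_x = np.cross(e_long, e_z)
    rot = np.stack([e_x, e_long, e_z])  # rows: new x, y, z axes
    return (coords - origin) @ rot.T


def build_peptide(conformation: str = "beta", seed: int = 0,
                  resnames: Sequence[str] = KLVFFAE_RESNAMES,
                  max_retries: int = 50) -> np.ndarray:
    """Coordinates (nm) of one peptide in a planted conformation.

    'beta' uses (φ, ψ) = (-139°, +135°); 'bent' a flat-lying (-75°, -40°)
    geometry with both Phe pseudo-atoms coplanar at minimal z; 'coil' draws
    dihedrals uniformly with clash rejection.  Deterministic given the seed.
    """
    R = len(resnames)
    if conformation == "beta":
        phi, psi = BETA_PHI_PSI
        coords = _assemble(_build_backbone([phi] * R, [psi] * R))
        return _orient(coords, resnames, flat=False)
    if conformation in ("bent", "surface-bent"):
        phi, psi = BENT_PHI_PSI
        coords = _assemble(_build_backbone([phi] * R, [psi] * R))
        return _orient(coords, resnames, flat=True)
    if conformation == "coil":
        rng = np.random.default_rng(seed)
        for _ in range(max_retries):
            phis = rng.uniform(-180.0, 180.0, R)
            psis = rng.uniform(-180.0, 180.0, R)
            coords = _assemble(_build_backbone(list(phis), list(psis)))
            ca = coords[_calpha_rows(R)]
            d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
            iu = np.triu_indices(R, k=2)
            if np.all(d[iu] > 0.25):
                return _orient(coords, resnames, flat=False)
        raise RuntimeError(
            f"coil build failed clash rejection after {max_retries} retries "
            f"(seed {seed})")
    raise ValueError(f"unknown conformation {conformation!r}")


def make_system(nmol: int, resnames: Sequence[str] = KLVFFAE_RESNAMES,
                surface: Optional[SurfaceModel] = None) -> MolecularSystem:
    """A MolecularSystem of ``nmol`` identical template peptides."""
    names, elements, rpos, rn, pep = [], [], [], [], []
    for p in range(nmol):
        for r, resname in enumerate(resnames, start=1):
            for name, el in zip(RESIDUE_ATOMS, RESIDUE_ELEMENTS):
                names.append(name)
                elements.append(el)
                rpos.append(r)
                rn.append(resname)
                pep.append(p)
    return MolecularSystem(names=names, elements=elements, residue_pos=rpos,
                           resnames=rn, peptide_index=pep, surface=surface)


def canonical_references() -> Dict[str, ReferenceDistances]:
    """The two shipped reference conformations for DRMSD classification.

    'fibril': ideal extended β-strand, a constructed stand-in for the
    strand conformation found in amyloid fibrils of this peptide.
    'surface': the flat-lying bent conformation a single molecule adopts
    on the gold surface (synthetic stand-in, built constructively).
    """
    R = len(KLVFFAE_RESNAMES)
    rows = _calpha_rows(R)
    return {
        "fibril": reference_from_coordinates(build_peptide("beta")[rows], "fibril"),
        "surface": reference_from_coordinates(build_peptide("bent")[rows], "surface"),
    }


# -- planted multi-peptide configurations -------------------------------------

@dataclass
class SyntheticSpec:
    """Planted ground truth for a synthetic trajectory.

    ``partitions`` is one partition (applied to every frame) or a list of
    per-frame partitions, each a list of peptide-index lists.  Conformations
    and adsorption states are per peptide; adsorption requires a surface.
    """

    nmol: int = 4
    n_frames: int = 5
    stride_ps: float = 1000.0
    partitions: Optional[Sequence] = None      # default: all monomers
    conformations: Optional[Sequence[str]] = None  # default: all "beta"
    adsorbed: Optional[Sequence[bool]] = None  # default: all True if surface
    surface: bool = False
    slab_nx: int = 20
    slab_ny: int = 12
    slab_layers: int = 5
    lattice_a: float = 4.14
    noise_nm: float = 0.0
    seed: int = 0
    box_z_nm: float = 12.0
    contact_target_nm: float = 0.30   # planted closest heavy-atom distance
    cluster_gap_nm: float = 1.2       # minimum free space between clusters

    def frame_partition(self, f: int) -> List[List[int]]:
        if self.partitions is None:
            return [[i] for i in range(self.nmol)]
        first = self.partitions[0]
        if first and isinstance(first[0], (list, tuple)):
            # per-frame list of partitions
            if len(self.partitions) != self.n_frames:
                raise ValueError(
                    f"got {len(self.partitions)} per-frame partitions for "
                    f"{self.n_frames} frames")
            return [list(c) for c in self.partitions[f]]
        if all(isinstance(c, (list, tuple)) for c in self.partitions):
            return [list(c) for c in self.partitions]  # one partition, all frames
        raise ValueError("partitions must be lists of peptide-index lists")

    def validate(self) -> None:
        for f in range(self.n_frames):
            part = self.frame_partition(f)
            flat = sorted(i for c in part for i in c)
            if flat != list(range(self.nmol)):
                raise ValueError(
                    f"frame {f}: partition {part} is not a partition of "
                    f"0..{self.nmol - 1}")
        if self.adsorbed is not None and not self.surface:
            raise ValueError("adsorption states need a surface")


def _axis_offset_for_contact(fixed_heavy: np.ndarray, moving: np.ndarray,
                             heavy_rows: np.ndarray, axis: int,
                             target: float) -> float:
    """Offset along ``axis`` placing the moving peptide at the target
    closest heavy-atom distance from the fixed heavy-atom set."""
    span = (fixed_heavy[:, axis].max() - moving[heavy_rows, axis].min())

    def min_dist(o):
        shifted = moving[heavy_rows].copy()
        shifted[:, axis] += o
        d = np.linalg.norm(fixed_heavy[:, None] - shifted[None, :], axis=-1)
        return d.min()

    lo, hi = span, span + 5.0
    while min_dist(hi) < target:
        hi += 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def plant_configuration(spec: SyntheticSpec) -> Tuple[Trajectory, dict]:
    """Build a trajectory realising the spec's planted truths.

    Cluster connectivity under the 0.4 nm heavy-atom criterion is verified
    against the planted partition on every noiseless frame before emission;
    after noise the check is repeated and recorded (``connectivity_ok``) but
    the planted truth is never silently changed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nmol = spec.nmol
    conformations = list(spec.conformations or ["beta"] * nmol)
    surface_model = None
    if spec.surface:
        _, surface_model = build_slab(spec.lattice_a, spec.slab_nx,
                                      spec.slab_ny, spec.slab_layers,
                                      top_z_nm=0.0)
        adsorbed = list(spec.adsorbed if spec.adsorbed is not None
                        else [True] * nmol)
    else:
        adsorbed = [False] * nmol

    system = make_system(nmol, surface=surface_model)
    R = system.residues_per_peptide
    heavy_rows_pp = np.array([k for k in range(R * ATOMS_PER_RESIDUE)
                              if RESIDUE_ATOMS[k % ATOMS_PER_RESIDUE] != "H"])

    # one template per peptide (coil templates differ per peptide via seed)
    templates = [build_peptide(conformations[p], seed=spec.seed * 1000 + p)
                 for p in range(nmol)]

    z_ads = 0.3      # Phe pseudo-atoms of adsorbed peptides above top layer
    z_des = 2.0      # detached peptides
    frames = []
    truth_frames = []
    for f in range(spec.n_frames):
        part = sorted((sorted(c) for c in spec.frame_partition(f)),
                      key=lambda c: (-len(c), c[0]))
        coords = np.zeros((system.n_atoms, 3))

        # phase 1: assemble each cluster as a block anchored at the origin.
        # Adsorbed members form the base x-chain; non-adsorbed members of a
        # mixed cluster stack in z on top of it (multilayer geometry).
        blocks = []
        for cluster in part:
            any_ads = spec.surface and any(adsorbed[p] for p in cluster)
            order = sorted(cluster, key=lambda p: (not adsorbed[p], p)) \
                if any_ads else list(cluster)
            placed_heavy = None
            prev_heavy = None
            block = {}
            # serpentine chaining: fill an x-row of side-by-side peptides,
            # wrap to the next y-row when the row would outgrow the cell
            max_row_w = (surface_model.lx - 1.2 if surface_model is not None
                         else np.inf)
            # solution clusters: near-square sheets stacked in z
            per_row = (np.inf if spec.surface
                       else int(np.ceil(np.sqrt(len(order)))))
            row_start = None
            row_count = 0
            for k, p in enumerate(order):
                tpl = templates[p].copy()
                stack = any_ads and not adsorbed[p]
                if spec.surface:
                    zbase = z_ads if adsorbed[p] else z_des
                else:
                    zbase = spec.box_z_nm / 2.0
                tpl[:, 1] -= tpl[:, 1].min()
                if k == 0:
                    tpl[:, 2] += zbase - tpl[:, 2].min()
                    tpl[:, 0] -= tpl[:, 0].min()
                    row_start = 0.0
                    row_count = 1
                elif stack:
                    tpl[:, 2] -= tpl[:, 2].min()  # z set purely by chaining
                    tpl[:, 0] -= tpl[:, 0].min()
                    tpl[:, 2] += _axis_offset_for_contact(
                        prev_heavy, tpl, heavy_rows_pp, 2,
                        spec.contact_target_nm)
                else:
                    tpl[:, 2] += zbase - tpl[:, 2].min()
                    width = tpl[:, 0].max() - tpl[:, 0].min()
                    row_w = prev_heavy[:, 0].max() - row_start
                    if (row_w + width + spec.contact_target_nm > max_row_w
                            or row_count >= per_row):
                        # row full: surface clusters wrap in-plane (y),
                        # solution clusters stack sheets in z (compact block)
                        wrap_ax = 1 if spec.surface else 2
                        tpl[:, 0] += row_start - tpl[:, 0].min()
                        tpl[:, wrap_ax] -= tpl[:, wrap_ax].min()
                        tpl[:, wrap_ax] += _axis_offset_for_contact(
                            prev_heavy, tpl, heavy_rows_pp, wrap_ax,
                            spec.contact_target_nm)
                        row_start = tpl[:, 0].min()
                        row_count = 1
                    else:
                        row_count += 1
                        # stay in the previous member's row (and layer)
                        tpl[:, 1] += prev_heavy[:, 1].min() - tpl[:, 1].min()
                        tpl[:, 2] += prev_heavy[:, 2].min() - tpl[:, 2].min()
                        tpl[:, 0] += _axis_offset_for_contact(
                            prev_heavy, tpl, heavy_rows_pp, 0,
                            spec.contact_target_nm)
                block[p] = tpl
                new_heavy = tpl[heavy_rows_pp]
                prev_heavy = new_heavy
                placed_heavy = (new_heavy if placed_heavy is None
                                else np.vstack([placed_heavy, new_heavy]))
            allxy = np.vstack(list(block.values()))
            blocks.append((block, allxy[:, 0].max() - allxy[:, 0].min(),
                           allxy[:, 1].max() - allxy[:, 1].min()))

        # phase 2: arrange blocks on a grid that fits the periodic cell
        nblocks = len(blocks)
        wmax = max(b[1] for b in blocks)
        dmax = max(b[2] for b in blocks)
        if surface_model is not None:
            lx, ly = surface_model.lx, surface_model.ly
            plan = None
            for gap in np.arange(spec.cluster_gap_nm, 0.44, -0.05):
                for ncols in range(nblocks, 0, -1):
                    nrows = -(-nblocks // ncols)
                    if (ncols * (wmax + gap) <= lx
                            and nrows * (dmax + gap) <= ly):
                        plan = (ncols, nrows, gap)
                        break
                if plan:
                    break
            if plan is None:
                raise RuntimeError(
                    f"infeasible packing at frame {f}: {nblocks} clusters of "
                    f"footprint {wmax:.2f} x {dmax:.2f} nm do not fit the "
                    f"{lx:.2f} x {ly:.2f} nm cell")
            ncols, nrows, gap = plan
        else:
            gap = spec.cluster_gap_nm
            ncols = int(np.ceil(np.sqrt(nblocks)))
            nrows = -(-nblocks // ncols)
        pitch_x, pitch_y = wmax + gap, dmax + gap
        for bi, (block, _, _) in enumerate(blocks):
            ox = 0.5 * gap + (bi % ncols) * pitch_x
            oy = 0.5 * gap + (bi // ncols) * pitch_y
            for p, tpl in block.items():
                shifted = tpl.copy()
                shifted[:, 0] += ox
                shifted[:, 1] += oy
                coords[system.peptide_atoms[p]] = shifted

        if surface_model is not None:
            box = Box.surface((surface_model.lx, surface_model.ly, spec.box_z_nm))
        else:
            extent = np.array([ncols * pitch_x, nrows * pitch_y, spec.box_z_nm])
            box = Box.solution(np.maximum(extent, coords.max(axis=0) + 0.5))
        frame = Frame(time=f * spec.stride_ps, coords=coords, box=box)

        realised = partition_frame(frame, system)
        planted = sorted((tuple(c) for c in part), key=lambda c: (-len(c), c[0]))
        if [tuple(c) for c in realised.clusters] != planted:
            raise RuntimeError(
                f"infeasible packing at frame {f}: planted {planted}, "
                f"realised {realised.clusters}")
        connectivity_ok = True
        if spec.noise_nm > 0:
            frame = Frame(time=frame.time,
                          coords=coords + rng.normal(0.0, spec.noise_nm,
                                                     coords.shape),
                          box=box)
            noisy = partition_frame(frame, system)
            connectivity_ok = [tuple(c) for c in noisy.clusters] == planted
        frames.append(frame)
        truth_frames.append({"partition": [list(c) for c in planted],
                             "connectivity_ok": connectivity_ok})

    quadrant = {"beta": "upper_left", "bent": "lower_left", "coil": None}
    if spec.surface:
        if all(adsorbed):
            agg_label = "monolayer"
        elif any(adsorbed):
            agg_label = "multilayer"
        else:
            agg_label = "detached"
    else:
        agg_label = None
    truth = {
        "nmol": nmol,
        "conformations": conformations,
        "quadrants": [quadrant[c] for c in conformations],
        "adsorbed": adsorbed,
        "aggregate_label": agg_label,
        "frames": truth_frames,
        "seed": spec.seed,
        "noise_nm": spec.noise_nm,
    }
    return Trajectory(system, frames), truth


def build_antiparallel_dimer() -> Tuple[MolecularSystem, Frame]:
    """Two ideal β-strands in antiparallel register, H-bond-aligned.

    The second strand is the first rotated 180° about z through its centroid
    (reversing the chain direction in the sheet plane) and offset so backbone
    N-H···O=C pairs meet the geometric hydrogen-bond criterion.  The
    resulting interpeptide hydrogen bonds sit on the anti-diagonal of the
    residue map (a + b ≈ R + 1), the antiparallel-sheet signature.
    """
    a = build_peptide("beta")
    c = a.mean(axis=0)
    flip = np.diag([-1.0, -1.0, 1.0])
    b = (a - c) @ flip.T + c + np.array([0.40, -0.10, -0.05])
    system = make_system(2)
    coords = np.vstack([a, b]) + 2.0
    frame = Frame(time=0.0, coords=coords, box=Box.solution((10.0, 10.0, 10.0)))
    return system, frame


def write_ground_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
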