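"""Au(111) slab geometry and peptide-surface analyses.

The gold surface is a five-layer fcc(111) slab cut from a lattice with
parameter a = 4.14 Å: the in-plane nearest-neighbour spacing is a/√2 =
2.927 Å, layers are ABC-stacked with spacing a/√3, and the 20 × 12
rectangular supercell measures about 5.86 nm × 6.09 nm.  Peptide-surface
analyses (residue z-profiles, adsorption classification, areal density) are
all referenced to the z of the topmost atomic layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (DEFAULT_WINDOW_PS, Frame, MolecularSystem, SurfaceModel,
                   Trajectory)
from .clustering import partition_frame, CONTACT_CUTOFF_NM

AVOGADRO = 6.02214076e23

#: default peptide-surface contact threshold above the top layer (nm)
SURFACE_CONTACT_Z_NM = 0.5
#: a peptide is adsorbed when in surface contact in at least this fraction
#: of window frames
ADSORBED_PERSISTENCE = 0.5


def build_slab(a_angstrom: float = 4.14, nx: int = 20, ny: int = 12,
               layers: int = 5, top_z_nm: float = 0.0) -> Tuple[np.ndarray, SurfaceModel]:
    """Build an ABC-stacked fcc(111) slab; coordinates in nm.

    The rectangular surface cell holds two atoms per layer with vectors
    (d, 0) and (0, √3 d), d = a/√2, so the in-plane dimensions are
    Lx = nx·d and Ly = ny·√3·d and the atom count is nx·ny·layers·2.
    """
    if min(a_angstrom, nx, ny, layers) <= 0:
        raise ValueError("slab parameters must be positive")
    d = a_angstrom / np.sqrt(2.0) / 10.0       # NN spacing, nm
    dz = a_angstrom / np.sqrt(3.0) / 10.0      # (111) interlayer spacing, nm
    lx, ly = nx * d, ny * np.sqrt(3.0) * d
    basis = np.array([[0.0, 0.0], [0.5 * d, 0.5 * np.sqrt(3.0) * d]])
    stack_shift = np.array([0.5 * d, d / (2.0 * np.sqrt(3.0))])
    coords = []
    for k in range(layers):
        off = (k * stack_shift) % np.array([d, np.sqrt(3.0) * d])
        z = top_z_nm - k * dz
        for i in range(nx):
            for j in range(ny):
                cell = np.array([i * d, j * np.sqrt(3.0) * d])
                for b in basis:
                    xy = (cell + b + off) % np.array([lx, ly])
                    coords.append([xy[0], xy[1], z])
    coords = np.array(coords)
    model = SurfaceModel(lattice_a=a_angstrom, nx=nx, ny=ny, layers=layers,
                         top_z=top_z_nm, lx=lx, ly=ly, atom_positions=coords)
    return coords, model


def nearest_neighbour_spacing(a_angstrom: float) -> float:
    """In-plane nearest-neighbour distance of an fcc(111) surface (Å)."""
    return a_angstrom / np.sqrt(2.0)


def surface_density(n_peptides: int, lx_nm: float, ly_nm: float) -> float:
    """Areal peptide density n / (N_A · A) in mol m⁻²."""
    if lx_nm <= 0 or ly_nm <= 0:
        raise ValueError("surface dimensions must be positive")
    area_m2 = lx_nm * ly_nm * 1e-18
    return n_peptides / (AVOGADRO * area_m2)


@dataclass
class ZProfile:
    """Window-mean residue heights above the top gold layer, plus the full
    per-peptide centre-of-mass z time series."""

    residue_mean_z: np.ndarray    # (n_peptides, R), nm above top layer
    labels: List[str]
    com_times: np.ndarray         # (n_frames,) ps, full trajectory
    com_z: np.ndarray             # (n_frames, n_peptides) nm above top layer
    window_start: float
    window_end: float


def _require_surface(system: MolecularSystem) -> SurfaceModel:
    if system.surface is None:
        raise ValueError("this analysis needs a surface; the system has none")
    return system.surface


def z_profile(traj: Trajectory, window_ps: Optional[float] = DEFAULT_WINDOW_PS,
              allow_short: bool = False) -> ZProfile:
    """Residue COM heights (window mean) and peptide COM z series."""
    system = traj.system
    surf = _require_surface(system)
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    R = system.residues_per_peptide
    nmol = system.n_peptides
    res_acc = np.zeros((nmol, R))
    for fr in frames:
        for p in range(nmol):
            for r in range(1, R + 1):
                idx = system.residue_atoms[p][r]
                w = system.masses[idx]
                res_acc[p, r - 1] += np.average(fr.coords[idx, 2], weights=w)
    res_acc /= len(frames)
    com_z = np.empty((len(traj), nmol))
    for fi, fr in enumerate(traj):
        for p in range(nmol):
            idx = system.peptide_atoms[p]
            com_z[fi, p] = np.average(fr.coords[idx, 2], weights=system.masses[idx])
    return ZProfile(residue_mean_z=res_acc - surf.top_z,
                    labels=system.residue_labels(),
                    com_times=traj.times, com_z=com_z - surf.top_z,
                    window_start=frames[0].time, window_end=frames[-1].time)


@dataclass
class AdsorptionReport:
    adsorbed: np.ndarray            # (n_peptides,) bool
    contact_fraction: np.ndarray    # fraction of window frames in contact
    aggregate_label: str            # "monolayer" | "multilayer" | "detached"
    window_start: float
    window_end: float


def classify_adsorption(traj: Trajectory,
                        window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                        contact_z: float = SURFACE_CONTACT_Z_NM,
                        persistence: float = ADSORBED_PERSISTENCE,
                        cutoff: float = CONTACT_CUTOFF_NM,
                        allow_short: bool = False) -> AdsorptionReport:
    """Per-peptide adsorption flags and the monolayer/multilayer verdict.

    A peptide is adsorbed when any of its heavy atoms sits within
    ``contact_z`` of the top gold layer in at least ``persistence`` of the
    window frames.  An aggregate is a monolayer when every adsorbed-phase
    peptide is in surface contact; if no peptide is adsorbed the system is
    detached.
    """
    system = traj.system
    surf = _require_surface(system)
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    nmol = system.n_peptides
    hits = np.zeros(nmol)
    for fr in frames:
        for p in range(nmol):
            zmin = fr.coords[system.peptide_heavy[p], 2].min() - surf.top_z
            if zmin <= contact_z:
                hits[p] += 1
    frac = hits / len(frames)
    adsorbed = frac >= persistence
    if not adsorbed.any():
        label = "detached"
    elif adsorbed.all():
        label = "monolayer"
    else:
        label = "multilayer"
    return AdsorptionReport(adsorbed=adsorbed, contact_fraction=frac,
                            aggregate_label=label,
                            window_start=frames[0].time, window_end=frames[-1].time)
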