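"""Reading and writing of structures and trajectories.

MDAnalysis does the file-format work (PDB, GRO, XTC/DCD, multi-model PDB);
this module maps between its universes and the internal nm-based data model.
Coordinates are converted to nm at the I/O boundary regardless of the source
unit (Å for PDB, nm for GRO; MDAnalysis normalises both to Å).
"""

from __future__ import annotations

import os
import warnings
from typing import Optional, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .core import (Box, Frame, MolecularSystem, SurfaceModel, Trajectory,
                   mass_of_element)

ANGSTROM_PER_NM = 10.0

#: residue names excluded from the peptide set (solvent, ions)
_SOLVENT_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP4", "TIP5", "SPC",
                     "NA", "CL", "NA+", "CL-", "K+", "MG2", "ION"}

_TWO_LETTER_ELEMENTS = ("AU", "NA", "CL", "MG", "ZN", "FE", "BR", "CA")


def element_from_name(name: str, resname: str = "") -> str:
    """PDB-style element assignment from an atom name.

    Leading digits are stripped; two-letter metal/halide symbols are
    recognised when the residue name supports them (e.g. Au slabs, ions), so
    that 'CA' in an amino acid stays carbon while 'AU' in a gold slab is gold.
    """
    nm = name.strip().upper().lstrip("0123456789")
    rn = resname.strip().upper()
    if not nm:
        return "X"
    if nm[:2] in _TWO_LETTER_ELEMENTS and (rn.startswith(nm[:2]) or rn in _SOLVENT_RESNAMES):
        return nm[:2]
    return nm[0]


def _atom_elements(universe) -> list:
    atoms = universe.atoms
    try:
        elements = [str(e) if str(e).strip() else None for e in atoms.elements]
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [None] * len(atoms)
    out = []
    for el, a in zip(elements, atoms):
        out.append(el.upper() if el else element_from_name(a.name, a.resname))
    return out


def _chain_of(atom) -> str:
    try:
        cid = atom.chainID
        if cid and cid.strip():
            return cid.strip()
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    try:
        seg = atom.segid
        if seg and seg.strip() and seg.strip() not in ("SYSTEM",):
            return seg.strip()
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    return ""


def load_system(topology_path: str, peptide_selection: Optional[str] = None) -> MolecularSystem:
    """Read a PDB/GRO topology into a MolecularSystem.

    Peptide copies are identified by chain/segment ID when present, else by
    residue-numbering restarts (GRO files often lack chain IDs).  Gold atoms
    are excluded from the peptide set and used to build the SurfaceModel.
    Solvent and ions are dropped.
    """
    if not os.path.exists(topology_path):
        raise FileNotFoundError(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(topology_path)
    elements = _atom_elements(u)

    au_idx, pep_idx = [], []
    if peptide_selection:
        selected = set(u.select_atoms(peptide_selection).indices)
    else:
        selected = None
    for a, el in zip(u.atoms, elements):
        if el == "AU" or a.resname.strip().upper().startswith("AU"):
            au_idx.append(a.index)
        elif a.resname.strip().upper() in _SOLVENT_RESNAMES:
            continue
        elif selected is None or a.index in selected:
            pep_idx.append(a.index)
    if not pep_idx:
        raise ValueError(f"no peptide atoms found in {topology_path}")

    # split peptide residues into copies
    atoms = u.atoms[pep_idx]
    pep_of_atom, chain_of_atom, rpos_of_atom = [], [], []
    pep, rpos = 0, 0
    prev_resid, prev_chain = None, None
    res_of_atom = atoms.resindices
    current_res = None
    for a in atoms:
        chain = _chain_of(a)
        if a.resindex != current_res:
            current_res = a.resindex
            restart = prev_resid is not None and a.resid <= prev_resid
            chain_change = prev_chain is not None and chain != prev_chain
            if restart or chain_change:
                pep += 1
                rpos = 1
            else:
                rpos = rpos + 1 if prev_resid is not None else 1
            prev_resid, prev_chain = a.resid, chain
        pep_of_atom.append(pep)
        rpos_of_atom.append(rpos)
        chain_of_atom.append(chain or chr(ord("A") + pep % 26))

    pep_elements = [elements[i] for i in pep_idx]
    try:
        masses = [float(m) for m in atoms.masses]
        if any(m <= 0 for m in masses):
            raise ValueError
    except (ValueError, AttributeError, mda.exceptions.NoDataError):
        masses = [mass_of_element(e) for e in pep_elements]

    surface = None
    if au_idx:
        au_pos = u.atoms[np.array(au_idx)].positions / ANGSTROM_PER_NM
        surface = SurfaceModel.from_positions(au_pos)

    system = MolecularSystem(
        names=[a.name for a in atoms], elements=pep_elements,
        residue_pos=rpos_of_atom, resnames=[a.resname for a in atoms],
        peptide_index=pep_of_atom, chain_tags=chain_of_atom,
        masses=masses, surface=surface)
    system.source_path = topology_path
    system._atom_indices = np.array(pep_idx, dtype=int)
    system._au_indices = np.array(au_idx, dtype=int)
    return system


def _frame_box(dimensions, surface_present: bool) -> Box:
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        lengths = (100.0, 100.0, 100.0)  # effectively non-periodic
    else:
        lengths = np.asarray(dimensions[:3], float) / ANGSTROM_PER_NM
    flags = (True, True, False) if surface_present else (True, True, True)
    return Box(lengths, flags)


def load_trajectory(system: MolecularSystem, traj_path: str,
                    dt_ps: Optional[float] = None) -> Trajectory:
    """Read a trajectory (XTC/DCD/multi-model PDB) against a loaded system.

    ``dt_ps`` overrides the frame times for formats that carry no physical
    time (e.g. multi-model PDB, where readers report frame numbers).
    """
    if not os.path.exists(traj_path):
        raise FileNotFoundError(traj_path)
    top = getattr(system, "source_path", None)
    if top is None:
        raise ValueError("system was not loaded from a file; cannot bind a trajectory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(top, traj_path)
    sel = getattr(system, "_atom_indices")
    if u.atoms.n_atoms < (sel.max() + 1):
        raise ValueError(
            f"atom count mismatch: trajectory {traj_path} has {u.atoms.n_atoms} "
            f"atoms, topology expects at least {sel.max() + 1}")
    frames, times = [], []
    surface_present = system.surface is not None
    for i, ts in enumerate(u.trajectory):
        t = float(i * dt_ps) if dt_ps is not None else float(ts.time)
        coords = u.atoms.positions[sel] / ANGSTROM_PER_NM
        frames.append(Frame(time=t, coords=coords,
                            box=_frame_box(ts.dimensions, surface_present)))
        times.append(t)
    if not frames:
        raise ValueError(f"no frames in trajectory {traj_path}")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError(f"non-monotonic frame times in {traj_path}: {times[:5]}...")
    return Trajectory(system, frames)


# -- writing ------------------------------------------------------------------

def _build_universe(system: MolecularSystem, include_surface: bool = True):
    """Assemble an MDAnalysis universe mirroring the system (slab included)."""
    n_pep_atoms = system.n_atoms
    slab = system.surface.atom_positions if (
        include_surface and system.surface is not None
        and system.surface.atom_positions is not None) else None
    n_slab = 0 if slab is None else len(slab)
    n_atoms = n_pep_atoms + n_slab

    resx, res_seg, resids, resnames, segids = [], [], [], [], []
    res_counter = -1
    prev = None
    for i in range(n_pep_atoms):
        key = (int(system.peptide_index[i]), int(system.residue_pos[i]))
        if key != prev:
            res_counter += 1
            prev = key
            resids.append(int(system.residue_pos[i]))
            resnames.append(str(system.resnames[i]))
            res_seg.append(int(system.peptide_index[i]))
        resx.append(res_counter)
    n_pep_res = res_counter + 1
    n_seg = system.n_peptides
    segids = [chr(ord("A") + p % 26) for p in range(n_seg)]
    if n_slab:
        resx.extend([n_pep_res] * n_slab)
        resids.append(1)
        resnames.append("AU")
        res_seg.append(n_seg)
        segids.append("Z")
        n_seg += 1
        n_pep_res += 1

    u = mda.Universe.empty(n_atoms, n_residues=n_pep_res, n_segments=n_seg,
                           atom_resindex=np.array(resx),
                           residue_segindex=np.array(res_seg),
                           trajectory=True)
    names = list(system.names) + ["AU"] * n_slab
    elements = list(system.elements) + ["AU"] * n_slab
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("segids", segids)
    u.add_TopologyAttr("chainIDs", [segids[s] for s in
                                    [res_seg[r] for r in resx]])
    u.add_TopologyAttr("masses", list(system.masses) + [196.967] * n_slab)
    return u, slab


def _frame_positions_angstrom(system, coords_nm, slab):
    pos = coords_nm
    if slab is not None:
        pos = np.vstack([coords_nm, slab])
    return pos * ANGSTROM_PER_NM


def write_structure(system: MolecularSystem, frame: Frame, path: str) -> None:
    """Write one frame as GRO or PDB (extension-dispatched); slab included."""
    u, slab = _build_universe(system)
    u.atoms.positions = _frame_positions_angstrom(system, frame.coords, slab)
    u.dimensions = np.concatenate([frame.box.lengths * ANGSTROM_PER_NM,
                                   [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write all frames as a multi-model PDB or XTC trajectory.

    XTC carries the frame times (uniform stride assumed); multi-model PDB
    stores frames only, so readers must be given the stride back.
    """
    system = traj.system
    u, slab = _build_universe(system)
    coords = np.array([_frame_positions_angstrom(system, fr.coords, slab)
                       for fr in traj.frames])
    dims = np.array([np.concatenate([fr.box.lengths * ANGSTROM_PER_NM,
                                     [90.0, 90.0, 90.0]]) for fr in traj.frames])
    dt = traj.stride_ps if len(traj) > 1 else 1.0
    u.load_new(coords, format=MemoryReader, dimensions=dims, dt=dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=u.atoms.n_atoms, multiframe=True) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def write_labelled_matrix(matrix: np.ndarray, labels: Sequence[str], path: str) -> None:
    """CSV matrix with residue labels as header row and first column."""
    import pandas as pd
    pd.DataFrame(np.asarray(matrix), index=list(labels),
                 columns=list(labels)).to_csv(path, float_format="%.6g")
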