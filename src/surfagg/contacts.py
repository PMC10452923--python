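"""Intermolecular residue-residue contact maps and hydrogen-bond maps.

Contacts use the same strict heavy-atom criterion as clustering (< 4 Å by
default).  Hydrogen bonds use a geometric criterion — donor-acceptor
distance <= 3.5 Å and hydrogen-donor-acceptor angle <= 30° — applied to
backbone N-H donors and backbone C=O acceptors (side-chain donors/acceptors
of Lys/Glu by flag).  Intra-peptide pairs are excluded everywhere: the maps
are evidence of how *different* peptides pack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core import (CONTACT_CUTOFF_NM, DEFAULT_WINDOW_PS, Frame,
                   MolecularSystem, Trajectory, minimum_image_shift,
                   pairwise_min_image_distances)

HBOND_DA_CUTOFF_NM = 0.35
HBOND_ANGLE_CUTOFF_DEG = 30.0


@dataclass
class ContactMap:
    """R x R matrix of interpeptide residue-residue contact frequencies.

    Entry (a, b) is the fraction of (window frame, unordered peptide pair)
    combinations in which residue position a of one peptide touches residue
    position b of the other, in either direction — so the matrix is
    symmetric and entries lie in [0, 1] under frequency normalization.
    """

    matrix: np.ndarray
    labels: List[str]
    window_start: float
    window_end: float
    normalization: str = "frequency"  # or "count"


@dataclass
class HBondMap:
    """R x R matrix of mean interpeptide hydrogen-bond counts per frame."""

    matrix: np.ndarray
    labels: List[str]
    window_start: float
    window_end: float
    convention: str = "backbone"  # or "backbone+sidechain"


def _frame_residue_contacts(frame: Frame, system: MolecularSystem,
                            cutoff: float) -> np.ndarray:
    """Symmetrised boolean contact evidence summed over peptide pairs."""
    R = system.residues_per_peptide
    nmol = system.n_peptides
    acc = np.zeros((R, R))
    for i in range(nmol):
        for j in range(i + 1, nmol):
            hit = np.zeros((R, R), dtype=bool)
            for a in range(1, R + 1):
                ia = system.residue_atoms[i][a]
                ia = ia[system.heavy[ia]]
                for b in range(1, R + 1):
                    jb = system.residue_atoms[j][b]
                    jb = jb[system.heavy[jb]]
                    d = pairwise_min_image_distances(frame.coords[ia],
                                                     frame.coords[jb], frame.box)
                    if d.min() < cutoff:
                        hit[a - 1, b - 1] = True
            acc += (hit | hit.T)
    return acc


def residue_contact_map(traj: Trajectory, window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                        cutoff: float = CONTACT_CUTOFF_NM,
                        normalization: str = "frequency",
                        allow_short: bool = False) -> ContactMap:
    """Interpeptide residue-residue contact map over the trailing window."""
    if normalization not in ("frequency", "count"):
        raise ValueError(f"unknown normalization {normalization!r}")
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    system = traj.system
    R = system.residues_per_peptide
    nmol = system.n_peptides
    acc = np.zeros((R, R))
    for fr in frames:
        acc += _frame_residue_contacts(fr, system, cutoff)
    if normalization == "frequency":
        npairs = nmol * (nmol - 1) // 2
        acc /= (len(frames) * max(npairs, 1))
    return ContactMap(matrix=acc, labels=system.residue_labels(),
                      window_start=frames[0].time, window_end=frames[-1].time,
                      normalization=normalization)


def _donors_acceptors(system: MolecularSystem, peptide: int,
                      include_sidechain: bool) -> Tuple[list, list]:
    """(donor N, its H, residue pos) triples and (acceptor O, residue pos) pairs.

    Backbone amide N paired with the hydrogen bonded to it (closest H in the
    residue is resolved per-frame); at this resolution side-chain terms use
    the Lys/Glu pseudo-atoms when requested and present.
    """
    donors, acceptors = [], []
    idx = system.peptide_atoms[peptide]
    for r, atoms in system.residue_atoms[peptide].items():
        names = system.names[atoms]
        n_at = atoms[names == "N"]
        amide_h = ("H", "HN", "H1", "H2", "H3", "HT1", "HT2", "HT3")
        h_at = atoms[(system.elements[atoms] == "H") & np.isin(names, amide_h)]
        o_at = atoms[names == "O"]
        if len(n_at) and len(h_at):
            donors.append((int(n_at[0]), [int(h) for h in h_at], int(r)))
        for o in o_at:
            acceptors.append((int(o), int(r)))
        if include_sidechain:
            resname = str(system.resnames[atoms[0]]).upper()
            sc = atoms[np.isin(names, ("CB", "NZ", "OE1", "OE2", "OXT"))]
            if resname == "GLU":
                for a in atoms[np.isin(names, ("OE1", "OE2"))]:
                    acceptors.append((int(a), int(r)))
    return donors, acceptors


def hydrogen_bond_map(traj: Trajectory, window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                      d_cut: float = HBOND_DA_CUTOFF_NM,
                      angle_cut: float = HBOND_ANGLE_CUTOFF_DEG,
                      include_sidechain: bool = False,
                      allow_short: bool = False) -> HBondMap:
    """Mean interpeptide hydrogen-bond counts per frame, by residue pair.

    A bond D-H...A is counted when the donor-acceptor heavy-atom distance is
    <= d_cut and the H-D-A angle is <= angle_cut.  Requires hydrogens in the
    topology.
    """
    system = traj.system
    if not np.any(system.elements == "H"):
        raise ValueError(
            "topology contains no hydrogens; hydrogen-bond analysis needs "
            "explicit H positions (use the heavy-atom contact map instead)")
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    R = system.residues_per_peptide
    nmol = system.n_peptides
    acc = np.zeros((R, R))
    per_pep = [_donors_acceptors(system, p, include_sidechain)
               for p in range(nmol)]
    cos_cut = np.cos(np.deg2rad(angle_cut))
    for fr in frames:
        x = fr.coords
        for i in range(nmol):
            for j in range(nmol):
                if i == j:
                    continue
                donors, _ = per_pep[i]
                _, acceptors = per_pep[j]
                for (dn, hs, ra) in donors:
                    for (ac, rb) in acceptors:
                        dvec = minimum_image_shift(x[ac] - x[dn], fr.box)
                        dda = np.linalg.norm(dvec)
                        if dda > d_cut or dda == 0.0:
                            continue
                        ok = False
                        for h in hs:
                            hvec = minimum_image_shift(x[h] - x[dn], fr.box)
                            nh = np.linalg.norm(hvec)
                            if nh == 0.0:
                                continue
                            cosang = float(np.dot(hvec, dvec) / (nh * dda))
                            if cosang >= cos_cut:
                                ok = True
                                break
                        if ok:
                            # donor residue ra of one peptide, acceptor rb of
                            # the other; symmetrise across the pair
                            acc[ra - 1, rb - 1] += 0.5
                            acc[rb - 1, ra - 1] += 0.5
    acc /= len(frames)
    return HBondMap(matrix=acc, labels=system.residue_labels(),
                    window_start=frames[0].time, window_end=frames[-1].time,
                    convention="backbone+sidechain" if include_sidechain else "backbone")
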