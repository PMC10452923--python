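"""Gyration-tensor shape descriptors for oligomers and single peptides.

The sorted square roots of the gyration-tensor eigenvalues (principal radii
Gmax >= Gmid >= Gmin, in nm) separate linear monolayer aggregates on a
surface (Gmin near the single-molecule value) from compact solution
aggregates.  Clusters are made whole across periodic boundaries before the
tensor is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .core import (DEFAULT_WINDOW_PS, Frame, MolecularSystem, Trajectory,
                   pairwise_min_image_distances)
from .clustering import CONTACT_CUTOFF_NM, contact_pairs


@dataclass
class GyrationResult:
    time: float
    members: tuple
    gmax: float  # nm, principal radii (sqrt of eigenvalues)
    gmid: float
    gmin: float
    rg: float
    eigenvalues: tuple  # nm^2, descending
    flagged: bool = False  # cluster spanned a full periodic axis; values suspect

    @property
    def radii(self):
        return (self.gmax, self.gmid, self.gmin)


def _unwrap_members(frame: Frame, system: MolecularSystem,
                    members: Sequence[int], cutoff: float) -> Dict[int, np.ndarray]:
    """Translate each member peptide by box vectors so the cluster is whole.

    Anchor = lowest peptide index; remaining peptides are attached
    breadth-first over the contact graph, each shifted so its closest
    heavy-atom pair to its already-placed neighbour obeys the minimum image.
    """
    members = sorted(members)
    box = frame.box
    adj = {m: [] for m in members}
    sub = [(i, j) for (i, j) in contact_pairs(frame, system, cutoff)
           if i in adj and j in adj]
    for i, j in sub:
        adj[i].append(j)
        adj[j].append(i)

    placed: Dict[int, np.ndarray] = {}

    def shift_for(ref_coords: np.ndarray, pep: int) -> np.ndarray:
        xj = frame.coords[system.peptide_heavy[pep]]
        d = pairwise_min_image_distances(ref_coords, xj, box)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        raw = xj[b] - ref_coords[a]
        shift = np.zeros(3)
        for ax in range(3):
            if box.periodic[ax]:
                shift[ax] = -box.lengths[ax] * np.round(raw[ax] / box.lengths[ax])
        return shift

    anchor = members[0]
    placed[anchor] = frame.coords[system.peptide_atoms[anchor]].copy()
    queue = [anchor]
    heavy_placed = {anchor: frame.coords[system.peptide_heavy[anchor]].copy()}
    while queue:
        i = queue.pop(0)
        for j in sorted(adj[i]):
            if j in placed:
                continue
            s = shift_for(heavy_placed[i], j)
            placed[j] = frame.coords[system.peptide_atoms[j]] + s
            heavy_placed[j] = frame.coords[system.peptide_heavy[j]] + s
            queue.append(j)
    # members not reachable through the contact graph: attach to the anchor
    for j in members:
        if j not in placed:
            s = shift_for(heavy_placed[anchor], j)
            placed[j] = frame.coords[system.peptide_atoms[j]] + s
            heavy_placed[j] = frame.coords[system.peptide_heavy[j]] + s
    return placed


def gyration_spectrum(frame: Frame, system: MolecularSystem,
                      members: Iterable[int], mass_weighted: bool = True,
                      cutoff: float = CONTACT_CUTOFF_NM) -> GyrationResult:
    """Principal radii of the (mass-weighted) gyration tensor of a cluster."""
    members = tuple(sorted(set(int(m) for m in members)))
    if not members:
        raise ValueError("gyration_spectrum requires a non-empty member set")
    placed = _unwrap_members(frame, system, members, cutoff)
    coords = np.vstack([placed[m] for m in members])
    idx = np.concatenate([system.peptide_atoms[m] for m in members])
    w = system.masses[idx] if mass_weighted else np.ones(len(idx))

    # a cluster that winds around a periodic axis cannot be unwrapped
    # consistently: some contact edge ends up longer than the cutoff in the
    # unwrapped coordinates, or the extent covers the whole axis
    flagged = False
    for ax in range(3):
        if frame.box.periodic[ax]:
            if coords[:, ax].max() - coords[:, ax].min() >= frame.box.lengths[ax]:
                flagged = True
    for (i, j) in contact_pairs(frame, system, cutoff):
        if i in placed and j in placed:
            hi = placed[i][system.heavy[system.peptide_atoms[i]]]
            hj = placed[j][system.heavy[system.peptide_atoms[j]]]
            d = np.linalg.norm(hi[:, None] - hj[None, :], axis=-1).min()
            if d >= cutoff:
                flagged = True

    com = np.average(coords, axis=0, weights=w)
    d = coords - com
    tensor = (w[:, None] * d).T @ d / w.sum()
    eig = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    eig = np.clip(eig, 0.0, None)
    radii = np.sqrt(eig)
    return GyrationResult(time=frame.time, members=members,
                          gmax=float(radii[0]), gmid=float(radii[1]),
                          gmin=float(radii[2]), rg=float(np.sqrt(eig.sum())),
                          eigenvalues=tuple(float(e) for e in eig),
                          flagged=flagged)


def single_peptide_reference_spectrum(
        traj: Trajectory, window_ps: Optional[float] = DEFAULT_WINDOW_PS,
        mass_weighted: bool = True, allow_short: bool = False) -> List[dict]:
    """Window-averaged principal radii of each individual peptide.

    The dashed single-molecule reference lines against which oligomer
    monolayer/ribbon signatures are judged.
    """
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    out = []
    for p in range(traj.system.n_peptides):
        vals = np.array([gyration_spectrum(fr, traj.system, (p,),
                                           mass_weighted=mass_weighted).radii
                         for fr in frames])
        rgs = [gyration_spectrum(fr, traj.system, (p,),
                                 mass_weighted=mass_weighted).rg for fr in frames]
        out.append({"peptide": p,
                    "gmax": float(vals[:, 0].mean()),
                    "gmid": float(vals[:, 1].mean()),
                    "gmin": float(vals[:, 2].mean()),
                    "rg": float(np.mean(rgs))})
    return out
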