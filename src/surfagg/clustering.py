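"""Oligomer detection by single-linkage clustering under the heavy-atom
contact criterion.

Two peptides belong to the same cluster when any pair of their heavy
(non-hydrogen) atoms is strictly closer than the cutoff (4 Å by default)
under the minimum-image convention; clusters are the connected components of
the resulting contact graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (CONTACT_CUTOFF_NM, DEFAULT_WINDOW_PS, Frame,
                   MolecularSystem, Trajectory, pairwise_min_image_distances)


@dataclass
class OligomerPartition:
    """Per-frame partition of peptide indices into contact clusters.

    Clusters are sorted by size descending, ties broken by smallest member
    index; each cluster's members are sorted ascending.
    """

    time: float
    clusters: List[Tuple[int, ...]]
    contact_pairs: List[Tuple[int, int]]

    @property
    def largest_size(self) -> int:
        return len(self.clusters[0]) if self.clusters else 0

    @property
    def sizes(self) -> List[int]:
        return [len(c) for c in self.clusters]

    def cluster_of(self, peptide: int) -> Tuple[int, ...]:
        for c in self.clusters:
            if peptide in c:
                return c
        raise KeyError(peptide)


@dataclass
class SizeHistogram:
    """P(s): probability that a randomly chosen peptide in a randomly chosen
    window frame belongs to a cluster of size s (peptide-weighted), or the
    fraction of clusters of size s (cluster-weighted)."""

    window_start: float
    window_end: float
    probabilities: np.ndarray  # index s-1 -> P(s), s = 1..Nmol
    weighting: str = "peptide"

    def p(self, s: int) -> float:
        return float(self.probabilities[s - 1])


def min_heavy_distance(frame: Frame, system: MolecularSystem, i: int, j: int) -> float:
    """Smallest heavy-atom minimum-image distance between peptides i and j (nm)."""
    xi = frame.coords[system.peptide_heavy[i]]
    xj = frame.coords[system.peptide_heavy[j]]
    return float(pairwise_min_image_distances(xi, xj, frame.box).min())


def peptide_contact(frame: Frame, system: MolecularSystem, i: int, j: int,
                    cutoff: float = CONTACT_CUTOFF_NM) -> bool:
    """True iff any heavy atom of peptide i is strictly within ``cutoff`` of
    any heavy atom of peptide j (minimum image).  Strict inequality: a pair
    at exactly the cutoff is not a contact."""
    if i == j:
        raise ValueError("peptide_contact requires two distinct peptides")
    return min_heavy_distance(frame, system, i, j) < cutoff


def contact_pairs(frame: Frame, system: MolecularSystem,
                  cutoff: float = CONTACT_CUTOFF_NM) -> List[Tuple[int, int]]:
    nmol = system.n_peptides
    pairs = []
    for i in range(nmol):
        for j in range(i + 1, nmol):
            if peptide_contact(frame, system, i, j, cutoff):
                pairs.append((i, j))
    return pairs


def partition_frame(frame: Frame, system: MolecularSystem,
                    cutoff: float = CONTACT_CUTOFF_NM) -> OligomerPartition:
    """Connected components of the peptide contact graph for one frame."""
    nmol = system.n_peptides
    pairs = contact_pairs(frame, system, cutoff)
    if pairs:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(nmol, nmol))
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(nmol)
    clusters = {}
    for p, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(p)
    ordered = sorted((tuple(sorted(c)) for c in clusters.values()),
                     key=lambda c: (-len(c), c[0]))
    return OligomerPartition(time=frame.time, clusters=list(ordered),
                             contact_pairs=pairs)


def largest_oligomer_series(traj: Trajectory,
                            cutoff: float = CONTACT_CUTOFF_NM) -> np.ndarray:
    """Largest cluster size for every frame (the aggregation time series)."""
    return np.array([partition_frame(fr, traj.system, cutoff).largest_size
                     for fr in traj], dtype=int)


def size_histogram(traj: Trajectory, cutoff: float = CONTACT_CUTOFF_NM,
                   window_ps: Optional[float] = DEFAULT_WINDOW_PS,
                   weighting: str = "peptide",
                   allow_short: bool = False) -> SizeHistogram:
    """Oligomer-size histogram over the trailing window.

    ``weighting='peptide'`` (default): P(s) = s * count(s) / (Nmol * frames),
    i.e. the probability a random peptide sits in a size-s cluster.
    ``weighting='cluster'``: fraction of observed clusters of size s.
    """
    if weighting not in ("peptide", "cluster"):
        raise ValueError(f"unknown weighting {weighting!r}")
    frames = traj.window_frames(window_ps, allow_short=allow_short)
    nmol = traj.system.n_peptides
    counts = np.zeros(nmol)
    total_clusters = 0
    for fr in frames:
        part = partition_frame(fr, traj.system, cutoff)
        for s in part.sizes:
            counts[s - 1] += 1
        total_clusters += len(part.clusters)
    if weighting == "peptide":
        probs = counts * np.arange(1, nmol + 1) / (nmol * len(frames))
    else:
        probs = counts / total_clusters
    return SizeHistogram(window_start=frames[0].time, window_end=frames[-1].time,
                         probabilities=probs, weighting=weighting)
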