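"""Stochastic bead-chain aggregator: overdamped Langevin dynamics.

One bead per residue (treated as a Cα-like heavy atom), harmonic bonds at
0.38 nm, a weak angle term, and residue-class pair interactions: the
hydrophobic core beads (L, V, F, A) attract each other, oppositely charged
termini (K, E) attract, like charges only repel.  With a slab present an
attractive wall acts on the Phe beads (strongest) so that surface runs
reproduce aggregation-on-surface kinetics.  This is a generator of
aggregation-like trajectories for exercising the pipeline, not a physical
model of the all-atom system.

The update is position Langevin: dx = (D/kT) F dt + sqrt(2 D dt) ξ with
D = kT/γ; deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (Box, Frame, MolecularSystem, SurfaceModel, Trajectory,
                   KLVFFAE_RESNAMES, minimum_image_shift)

HYDROPHOBIC = {"LEU", "VAL", "PHE", "ALA"}
POSITIVE = {"LYS"}
NEGATIVE = {"GLU", "ASP"}


@dataclass
class LangevinParams:
    """Parameters of the bead-chain simulator (nm, ps-like reduced time,
    kJ/mol energies; kT = 2.494 kJ/mol is 300 K)."""

    bond_length: float = 0.38
    bond_k: float = 500.0          # kJ/mol/nm^2
    angle_k: float = 5.0           # kJ/mol/rad^2, rest angle 180 deg
    epsilon_hydrophobic: float = 12.0   # well depth, hydrophobic pairs
    epsilon_charge: float = 8.0         # well depth, K-E pairs
    epsilon_wall: float = 25.0          # Phe-surface well depth
    epsilon_wall_other: float = 1.0     # other residues vs surface
    sigma: float = 0.34            # LJ sigma, nm (minimum at 0.38)
    lj_cutoff: float = 1.2         # nm
    wall_z0: float = 0.30          # preferred bead height above top layer, nm
    kT: float = 2.494
    friction: float = 5.0          # gamma; D = kT/gamma
    dt: float = 5.0e-4
    seed: int = 0

    def validate(self) -> None:
        if min(self.bond_k, self.angle_k, self.friction, self.dt) <= 0:
            raise ValueError("stiffnesses, friction and timestep must be positive")
        # stability: bond relaxation must be resolved by the timestep
        if self.bond_k * self.dt / self.friction > 0.5:
            raise ValueError("unstable parameters: bond_k*dt/friction > 0.5")


def make_bead_system(nmol: int, resnames: Sequence[str] = KLVFFAE_RESNAMES,
                     surface: Optional[SurfaceModel] = None) -> MolecularSystem:
    """One CA bead per residue per peptide."""
    names, elements, rpos, rn, pep = [], [], [], [], []
    for p in range(nmol):
        for r, resname in enumerate(resnames, start=1):
            names.append("CA")
            elements.append("C")
            rpos.append(r)
            rn.append(resname)
            pep.append(p)
    return MolecularSystem(names=names, elements=elements, residue_pos=rpos,
                           resnames=rn, peptide_index=pep, surface=surface)


def dilute_initial_coords(system: MolecularSystem, box: Box,
                          z: Optional[float] = None) -> np.ndarray:
    """Extended chains along x, spread evenly over the (y, z) cross-section
    so no pair is close under the minimum image.  ``z`` pins all chains to
    one height (surface runs); otherwise chains fill the box in z too."""
    nmol = system.n_peptides
    R = system.residues_per_peptide
    coords = np.zeros((system.n_atoms, 3))
    bl = 0.38
    if z is None:
        ny = int(np.ceil(np.sqrt(nmol)))
        nz = -(-nmol // ny)
    else:
        ny, nz = nmol, 1
    for p in range(nmol):
        gy = (p % ny + 0.5) * box.lengths[1] / ny
        gz = z if z is not None else (p // ny + 0.5) * box.lengths[2] / nz
        for r in range(R):
            coords[p * R + r] = (0.2 + r * bl, gy, gz)
    return coords


def _pair_epsilons(system: MolecularSystem, params: LangevinParams) -> np.ndarray:
    """Per-bead-pair well depths; zero means purely repulsive core."""
    n = system.n_atoms
    cls = []
    for rn in system.resnames:
        rn = str(rn).upper()
        if rn in HYDROPHOBIC:
            cls.append("h")
        elif rn in POSITIVE:
            cls.append("+")
        elif rn in NEGATIVE:
            cls.append("-")
        else:
            cls.append("0")
    eps = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = cls[i], cls[j]
            if a == "h" and b == "h":
                eps[i, j] = params.epsilon_hydrophobic
            elif {a, b} == {"+", "-"}:
                eps[i, j] = params.epsilon_charge
    same_pep = system.peptide_index[:, None] == system.peptide_index[None, :]
    eps[same_pep] = 0.0
    return eps


def _forces(x, system, params, box, eps, wall_eps, top_z):
    # overlapping beads produce NaN forces; the integrator detects the
    # non-finite coordinates and raises with step and seed, so silence the
    # intermediate warnings
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        return _forces_impl(x, system, params, box, eps, wall_eps, top_z)


def _forces_impl(x: np.ndarray, system: MolecularSystem, params: LangevinParams,
                 box: Box, eps: np.ndarray, wall_eps: np.ndarray,
                 top_z: Optional[float]):
    n = system.n_atoms
    R = system.residues_per_peptide
    f = np.zeros_like(x)
    energy = 0.0

    # bonds
    for p in range(system.n_peptides):
        rows = system.peptide_atoms[p]
        d = x[rows[1:]] - x[rows[:-1]]
        dist = np.linalg.norm(d, axis=1)
        dev = dist - params.bond_length
        energy += 0.5 * params.bond_k * np.sum(dev ** 2)
        fb = (params.bond_k * dev / dist)[:, None] * d
        np.add.at(f, rows[:-1], fb)
        np.add.at(f, rows[1:], -fb)
        # angles (rest 180 deg): harmonic in cos(theta)+1 for robustness
        if len(rows) >= 3:
            u = d[:-1]
            v = d[1:]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.sum(u * v, axis=1) / (nu * nv)
            energy += params.angle_k * np.sum(1.0 - c)
            dcdu = (v / nv[:, None] - (c / nu)[:, None] * u / nu[:, None]) / nu[:, None]
            dcdv = (u / nu[:, None] - (c / nv)[:, None] * v / nv[:, None]) / nv[:, None]
            ka = params.angle_k
            np.add.at(f, rows[:-2], -ka * dcdu)
            np.add.at(f, rows[1:-1], ka * (dcdu - dcdv))
            np.add.at(f, rows[2:], ka * dcdv)

    # nonbonded: WCA core for all inter-peptide pairs + LJ attraction by class
    disp = minimum_image_shift(x[:, None, :] - x[None, :, :], box)
    dist = np.sqrt(np.sum(disp ** 2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    inter = system.peptide_index[:, None] != system.peptide_index[None, :]
    sig = params.sigma
    within = inter & (dist < params.lj_cutoff)
    ii, jj = np.nonzero(within)
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    if len(ii):
        r = dist[ii, jj]
        e = eps[ii, jj]
        sr6 = (sig / r) ** 6
        rep_only = e == 0.0
        e_eff = np.where(rep_only, 1.0, e)
        # full LJ for attracting pairs; WCA (shifted, cut at minimum) otherwise
        lj_e = 4 * e_eff * (sr6 ** 2 - sr6)
        lj_f = 24 * e_eff * (2 * sr6 ** 2 - sr6) / r   # magnitude along disp
        rmin = sig * 2 ** (1 / 6)
        cut = rep_only & (r >= rmin)
        lj_e = np.where(cut, 0.0, np.where(rep_only, lj_e + e_eff, lj_e))
        lj_f = np.where(cut, 0.0, lj_f)
        energy += float(np.sum(lj_e))
        fpair = (lj_f / r)[:, None] * disp[ii, jj]
        np.add.at(f, ii, fpair)
        np.add.at(f, jj, -fpair)

    # wall: Gaussian well at wall_z0 above the top layer + steep repulsion
    if top_z is not None:
        z = x[:, 2] - top_z
        z = np.maximum(z, 0.05)
        w = 0.15
        g = np.exp(-((z - params.wall_z0) ** 2) / (2 * w * w))
        energy += float(np.sum(-wall_eps * g))
        fz = -wall_eps * g * (z - params.wall_z0) / (w * w)
        rep = (0.1 / z) ** 9
        energy += float(np.sum(rep))
        fz += 9.0 * rep / z
        f[:, 2] += fz
    return f, energy


def langevin_aggregate(params: LangevinParams, system: MolecularSystem,
                       x0: np.ndarray, box: Box, n_steps: int,
                       stride: int = 100, stride_ps: float = 10.0) -> Trajectory:
    """Run overdamped Langevin dynamics; emit every ``stride`` steps.

    Raises on NaN/overflow with the step and seed in the message.  The box
    is periodic as flagged; a slab (system.surface) adds the attractive wall
    in z acting most strongly on Phe beads.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    x = np.array(x0, dtype=float)
    if x.shape != (system.n_atoms, 3):
        raise ValueError("initial coordinates do not match the bead system")
    eps = _pair_epsilons(system, params)
    wall_eps = np.where(np.char.upper(system.resnames.astype(str)) == "PHE",
                        params.epsilon_wall, params.epsilon_wall_other)
    top_z = system.surface.top_z if system.surface is not None else None
    D = params.kT / params.friction
    noise_scale = np.sqrt(2.0 * D * params.dt)
    frames = [Frame(time=0.0, coords=x.copy(), box=box)]
    for step in range(1, n_steps + 1):
        f, _ = _forces(x, system, params, box, eps, wall_eps, top_z)
        drift = (D / params.kT) * f * params.dt
        # cap the deterministic displacement: steep core overlaps must relax
        # over several steps instead of catapulting beads across the box
        norm = np.linalg.norm(drift, axis=1, keepdims=True)
        drift *= np.minimum(1.0, 0.05 / np.maximum(norm, 1e-12))
        x = x + drift + noise_scale * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e4):
            raise FloatingPointError(
                f"coordinate overflow at step {step} (seed {params.seed}); "
                "reduce the timestep or interaction strengths")
        if step % stride == 0:
            frames.append(Frame(time=(step // stride) * stride_ps,
                                coords=x.copy(), box=box))
    return Trajectory(system, frames)


def total_energy(x: np.ndarray, system: MolecularSystem, params: LangevinParams,
                 box: Box) -> float:
    eps = _pair_epsilons(system, params)
    wall_eps = np.where(np.char.upper(system.resnames.astype(str)) == "PHE",
                        params.epsilon_wall, params.epsilon_wall_other)
    top_z = system.surface.top_z if system.surface is not None else None
    _, e = _forces(x, system, params, box, eps, wall_eps, top_z)
    return e
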