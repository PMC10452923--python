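"""Full-analysis orchestration: cluster -> shape -> contacts -> conformation
-> surface, with CSV/JSON outputs and a run manifest.

The output set is the analysis inventory of a surface-aggregation study:
largest-oligomer series, size histogram, gyration spectra, contact and
hydrogen-bond maps, DRMSD histograms per reference, Ramachandran density,
and (for surface systems) residue z-profiles and adsorption labels.  CSV and
JSON are the contract; plotting belongs downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, contacts, conformation, shape, surface as surface_mod
from .core import CONTACT_CUTOFF_NM, DEFAULT_WINDOW_PS, Trajectory
from .conformation import ReferenceDistances, load_reference
from .io import load_system, load_trajectory, write_labelled_matrix
from .synthetic import canonical_references

log = logging.getLogger("surfagg")


@dataclass
class RunConfig:
    topology: Optional[str] = None
    trajectory: Optional[str] = None
    out_dir: str = "surfagg_out"
    cutoff_nm: float = CONTACT_CUTOFF_NM
    window_ps: Optional[float] = DEFAULT_WINDOW_PS
    drmsd_bin_a: float = 0.1
    rama_bin_deg: float = 5.0
    hbond_d_cut_nm: float = 0.35
    hbond_angle_deg: float = 30.0
    hbond_sidechain: bool = False
    surface_contact_z_nm: float = 0.5
    size_weighting: str = "peptide"
    references: Dict[str, str] = field(default_factory=dict)  # label -> path
    dt_ps: Optional[float] = None
    seed: int = 0

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


#: which figure family of a surface-aggregation study each file answers
TRACEABILITY = {
    "largest_oligomer.csv": "largest-oligomer time series",
    "size_histogram.csv": "oligomer size histogram (trailing window)",
    "gyration.csv": "oligomer + single-molecule gyration spectra",
    "contact_map.csv": "intermolecular residue-residue contact map",
    "hbond_map.csv": "interpeptide hydrogen-bond map",
    "drmsd_hist_<ref>.csv": "DRMSD histograms vs reference conformations",
    "ramachandran.csv": "backbone (phi, psi) density and quadrant occupancy",
    "z_profile.csv": "residue heights above the gold top layer",
    "adsorption.csv": "peptide adsorption flags, monolayer/multilayer label",
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class AnalysisReport:
    out_dir: str
    outputs: Dict[str, str]
    summary: dict


def _resolve_references(config: RunConfig) -> List[ReferenceDistances]:
    if config.references:
        return [load_reference(path, label)
                for label, path in sorted(config.references.items())]
    return list(canonical_references().values())


def run_pipeline(config: RunConfig, traj: Optional[Trajectory] = None) -> AnalysisReport:
    """Run every analysis stage on a trajectory and write the output set.

    ``traj`` may be passed directly (synthetic runs); otherwise topology and
    trajectory paths from the config are loaded.  Deterministic given config
    and inputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if traj is None:
        if not config.topology or not config.trajectory:
            raise ValueError("config must name topology and trajectory files")
        log.info("loading %s / %s", config.topology, config.trajectory)
        system = load_system(config.topology)
        traj = load_trajectory(system, config.trajectory, dt_ps=config.dt_ps)
    system = traj.system
    window = config.window_ps
    span = traj.times[-1] - traj.times[0]
    allow_short = False
    if window is not None and span < window:
        log.warning("trajectory spans %.0f ps < %.0f ps window; using "
                    "trailing 20%%", span, window)
        allow_short = True
    outputs: Dict[str, str] = {}
    summary: dict = {"n_peptides": system.n_peptides,
                     "residues_per_peptide": system.residues_per_peptide,
                     "n_frames": len(traj), "surface": system.surface is not None}

    def path(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        outputs[name] = p
        return p

    # clustering
    sizes = clustering.largest_oligomer_series(traj, config.cutoff_nm)
    pd.DataFrame({"time_ps": traj.times, "largest_size": sizes}).to_csv(
        path("largest_oligomer.csv"), index=False)
    hist = clustering.size_histogram(traj, config.cutoff_nm, window,
                                     weighting=config.size_weighting,
                                     allow_short=allow_short)
    pd.DataFrame({"size": np.arange(1, system.n_peptides + 1),
                  "probability": hist.probabilities}).to_csv(
        path("size_histogram.csv"), index=False)
    summary["final_largest_size"] = int(sizes[-1])
    summary["size_histogram"] = hist.probabilities.tolist()

    # shape: per window frame, per cluster, plus single-molecule reference
    rows = []
    for fr in traj.window_frames(window, allow_short=allow_short):
        part = clustering.partition_frame(fr, system, config.cutoff_nm)
        for ci, cluster in enumerate(part.clusters):
            g = shape.gyration_spectrum(fr, system, cluster,
                                        cutoff=config.cutoff_nm)
            rows.append({"time_ps": fr.time, "cluster": ci,
                         "size": len(cluster), "gmax_nm": g.gmax,
                         "gmid_nm": g.gmid, "gmin_nm": g.gmin, "rg_nm": g.rg,
                         "eig_max_nm2": g.eigenvalues[0],
                         "eig_mid_nm2": g.eigenvalues[1],
                         "eig_min_nm2": g.eigenvalues[2],
                         "flagged": g.flagged})
    pd.DataFrame(rows).to_csv(path("gyration.csv"), index=False)
    singles = shape.single_peptide_reference_spectrum(traj, window,
                                                      allow_short=allow_short)
    pd.DataFrame(singles).to_csv(path("gyration_single.csv"), index=False)
    if rows:
        summary["mean_gyration_nm"] = {
            k: float(np.mean([r[k] for r in rows]))
            for k in ("gmax_nm", "gmid_nm", "gmin_nm")}
        summary["single_peptide_gyration_nm"] = {
            k: float(np.mean([s[k[:4].rstrip("_")] for s in singles]))
            for k in ("gmax_nm", "gmid_nm", "gmin_nm")}

    # contacts
    cmap = contacts.residue_contact_map(traj, window, config.cutoff_nm,
                                        allow_short=allow_short)
    write_labelled_matrix(cmap.matrix, cmap.labels, path("contact_map.csv"))
    has_h = bool(np.any(system.elements == "H"))
    if has_h:
        hmap = contacts.hydrogen_bond_map(
            traj, window, d_cut=config.hbond_d_cut_nm,
            angle_cut=config.hbond_angle_deg,
            include_sidechain=config.hbond_sidechain, allow_short=allow_short)
        write_labelled_matrix(hmap.matrix, hmap.labels, path("hbond_map.csv"))

    # conformation
    refs = _resolve_references(config)
    series = conformation.drmsd_histograms(traj, refs, window,
                                           bin_width_a=config.drmsd_bin_a,
                                           allow_short=allow_short)
    summary["drmsd"] = {}
    for label, s in series.items():
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        pd.DataFrame({"drmsd_A": centers, "probability": s.histogram}).to_csv(
            path(f"drmsd_hist_{label}.csv"), index=False)
        summary["drmsd"][label] = {"peak_A": s.peak_position,
                                   "mass_below_1A": s.mass_below(1.0)}
    summary["drmsd_bin_a"] = config.drmsd_bin_a
    rama = conformation.ramachandran(traj, window, config.rama_bin_deg,
                                     allow_short=allow_short)
    pd.DataFrame(rama.samples, columns=["phi_deg", "psi_deg"]).to_csv(
        path("ramachandran.csv"), index=False)
    summary["ramachandran_quadrants"] = rama.quadrant_occupancy

    # surface analyses
    if system.surface is not None:
        zp = surface_mod.z_profile(traj, window, allow_short=allow_short)
        pd.DataFrame(zp.residue_mean_z, columns=zp.labels).to_csv(
            path("z_profile.csv"), index_label="peptide")
        ads = surface_mod.classify_adsorption(
            traj, window, contact_z=config.surface_contact_z_nm,
            cutoff=config.cutoff_nm, allow_short=allow_short)
        pd.DataFrame({"peptide": np.arange(system.n_peptides),
                      "adsorbed": ads.adsorbed,
                      "contact_fraction": ads.contact_fraction}).to_csv(
            path("adsorption.csv"), index=False)
        summary["aggregate_label"] = ads.aggregate_label
        summary["surface_density_mol_m2"] = surface_mod.surface_density(
            system.n_peptides, system.surface.lx, system.surface.ly)
        # DRMSD split for peptides in surface contact
        in_contact = [int(p) for p in np.flatnonzero(ads.adsorbed)]
        if in_contact and len(in_contact) < system.n_peptides:
            split = conformation.drmsd_histograms(
                traj, refs, window, bin_width_a=config.drmsd_bin_a,
                peptides=in_contact, allow_short=allow_short)
            for label, s in split.items():
                centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
                pd.DataFrame({"drmsd_A": centers,
                              "probability": s.histogram}).to_csv(
                    path(f"drmsd_hist_{label}_surface_contact.csv"), index=False)

    manifest = {
        "config": config.resolved(),
        "inputs": {k: _sha256(v) for k, v in
                   (("topology", config.topology),
                    ("trajectory", config.trajectory)) if v},
        "window_ps": window, "window_fallback_trailing20": allow_short,
        "outputs": sorted(outputs),
        "traceability": TRACEABILITY,
        "summary": summary,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    outputs["manifest.json"] = os.path.join(config.out_dir, "manifest.json")
    return AnalysisReport(out_dir=config.out_dir, outputs=outputs, summary=summary)


def compare_runs(reports: Sequence[AnalysisReport]) -> pd.DataFrame:
    """Side-by-side comparison of two or more runs.

    Rows: DRMSD peak positions and sub-1 Å masses per reference, quadrant
    occupancies, mean gyration spectra.  Replicas are presented side by
    side, not pooled.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    bins = {r.summary.get("drmsd_bin_a") for r in reports}
    if len(bins) > 1:
        raise ValueError(
            f"reports use different DRMSD bin widths {sorted(bins)}; "
            "rebin with a common drmsd_bin_a before comparing")
    rows = {}
    for ri, rep in enumerate(reports):
        col = f"run{ri}:{os.path.basename(rep.out_dir.rstrip('/'))}"
        s = rep.summary
        for label, d in s.get("drmsd", {}).items():
            rows.setdefault(f"drmsd_peak_A[{label}]", {})[col] = d["peak_A"]
            rows.setdefault(f"drmsd_mass_below_1A[{label}]", {})[col] = d["mass_below_1A"]
        for q, v in s.get("ramachandran_quadrants", {}).items():
            rows.setdefault(f"rama_occupancy[{q}]", {})[col] = v
        for k, v in s.get("mean_gyration_nm", {}).items():
            rows.setdefault(f"mean_{k}", {})[col] = v
        if "aggregate_label" in s:
            rows.setdefault("aggregate_label", {})[col] = s["aggregate_label"]
    return pd.DataFrame(rows).T
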