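"""End-to-end pipeline: fixtures -> consensus -> trajectory analytics -> report.

A single YAML config drives every stage; all tunables default to the
standard values of the screening protocol (contact cutoff 3.5 Å, 240
density windows over [-120, 120] Å, consensus top_k 5 / min_metrics 3,
20 clusters).  The run is deterministic given the config seed and the
report JSON echoes every parameter used, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import consensus as cons
from . import fixtures, io, trajectory as trj

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "sorbscreen_out",
    "docking": {
        "n_ligands": 60,
        "n_conformations": 10,
        "n_grids": 2,
        "poses_per_run": 5,
        "n_planted": 5,
        "delta": -5.0,
        "policy": "best-per-run",
        "top_k": 5,
        "min_metrics": 3,
    },
    "capture": {
        "n_copies": 10,
        "n_frames": 60,
        "dt_ns": 1.0,
        "cutoff": 3.5,
        "captured_fraction": 0.8,
    },
    "brownian": {
        "n_particles": 50,
        "d_coeff": 0.1,
        "dt_ns": 0.1,
        "n_steps": 2000,
    },
    "density": {
        "n_windows": 240,
        "range": [-120.0, 120.0],
    },
    "cluster": {
        "n_clusters": 5,
        "n_frames": 30,
    },
}

_ALLOWED_KEYS = {
    None: set(DEFAULT_CONFIG),
    "docking": set(DEFAULT_CONFIG["docking"]),
    "capture": set(DEFAULT_CONFIG["capture"]) | {"traj", "selections"},
    "brownian": set(DEFAULT_CONFIG["brownian"]),
    "density": set(DEFAULT_CONFIG["density"]),
    "cluster": set(DEFAULT_CONFIG["cluster"]),
}


def validate_config(config: dict) -> dict:
    """Merge over the defaults; unknown keys raise with the offending names."""
    offending = [k for k in config if k not in _ALLOWED_KEYS[None]]
    for section, allowed in _ALLOWED_KEYS.items():
        if section is None or section not in config:
            continue
        offending += [f"{section}.{k}" for k in config[section] if k not in allowed]
    if offending:
        raise PipelineError("config", f"unknown keys: {sorted(offending)}")
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage on seeded fixtures and return the report dict."""
    cfg = validate_config(config or {})
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": cfg, "results": {}}

    # -- consensus on a planted docking table ------------------------------
    logger.info("stage docking: generating scores and selecting candidates")
    d = cfg["docking"]
    planted = tuple(f"L{i:04d}" for i in range(int(d["n_planted"])))
    scores = fixtures.gen_docking_scores(
        n_ligands=d["n_ligands"], n_conformations=d["n_conformations"],
        n_grids=d["n_grids"], poses_per_run=d["poses_per_run"],
        planted=planted, delta=d["delta"], seed=seed,
    )
    poses = [cons.DockingPose(str(r.ligand_id), int(r.conformation_id),
                              int(r.grid_id), int(r.pose_index), float(r.energy))
             for r in scores.itertuples(index=False)]
    vectors = cons.aggregate_poses(poses, policy=d["policy"])
    table = cons.fusion_table(vectors)
    result = cons.consensus_select(table, top_k=d["top_k"],
                                   min_metrics=d["min_metrics"])
    cons.write_fusion_csv(table, outdir / "fusion.csv")
    cons.write_consensus_csv(result, outdir / "consensus.csv")
    report["results"]["consensus"] = {
        "planted": list(planted),
        "selected": list(result.selected),
        "planted_recovered": sorted(set(planted) & set(result.selected)),
    }

    # -- capture kinetics ---------------------------------------------------
    c = cfg["capture"]
    if "traj" in c or "selections" in c:
        traj_path = c.get("traj")
        sel_path = c.get("selections")
        if not traj_path or not Path(traj_path).exists():
            raise PipelineError("capture", f"trajectory path missing: {traj_path!r}")
        if not sel_path or not Path(sel_path).exists():
            raise PipelineError("capture", f"selections path missing: {sel_path!r}")
        traj = io.read_trajectory(traj_path, sel_path)
        ground_truth = None
    else:
        n_copies, n_frames = int(c["n_copies"]), int(c["n_frames"])
        n_captured = int(round(c["captured_fraction"] * n_copies))
        schedule = {
            i: (1 + (i * (n_frames - 2)) // max(n_captured, 1)
                if i < n_captured else None)
            for i in range(n_copies)
        }
        traj, ground_truth = fixtures.gen_capture_traj(
            schedule, n_frames=n_frames, dt=c["dt_ns"],
            cutoff=c["cutoff"], seed=seed,
        )
    copy_groups = sorted(g for g in traj.groups if g.startswith("copy_"))
    if not copy_groups:
        raise PipelineError("capture", "no copy_* ligand groups in trajectory")
    series = trj.capture_count(traj, copy_groups, "matrix", cutoff=c["cutoff"])
    if ground_truth is not None and not np.array_equal(series.counts,
                                                       ground_truth.counts):
        raise PipelineError("capture", "counts disagree with the fixture schedule")
    half = trj.capture_halftime(series)
    io.write_timeseries_csv(series, outdir / "capture.csv")
    report["results"]["capture"] = {
        "half_time_ns": half if half != float("inf") else None,
        "max_captured": int(series.counts.max()),
        "n_copies": series.n_copies,
        "cutoff_A": series.cutoff,
    }

    # -- diffusion ----------------------------------------------------------
    b = cfg["brownian"]
    btraj = fixtures.gen_brownian_traj(
        n_particles=b["n_particles"], d_coeff=b["d_coeff"],
        dt=b["dt_ns"], n_steps=b["n_steps"], seed=seed,
    )
    # fit lags well below the trajectory length; long lags are poorly averaged
    curve = trj.msd(btraj, "ligand", max_lag=max(10, int(b["n_steps"]) // 20))
    est = trj.diffusion_coefficient(curve)
    io.write_msd_csv(curve, outdir / "msd.csv")
    report["results"]["diffusion"] = {
        "d_input_A2_per_ns": b["d_coeff"],
        "d_est_A2_per_ns": est.d_A2_per_ns,
        "d_est_cm2_per_s": est.d_cm2_per_s,
        "fit_window_ns": list(est.fit_window),
    }

    # -- density profile ----------------------------------------------------
    dn = cfg["density"]
    lo, hi = dn["range"]
    slabs = [(-20.0, -10.0, 1200.0), (0.0, 30.0, 3600.0)]
    straj = fixtures.gen_slab_traj(slabs, box=(100.0, 100.0, hi - lo), seed=seed)
    profile = trj.density_profile(straj, "all", axis="z",
                                  n_windows=int(dn["n_windows"]),
                                  coord_range=(lo, hi))
    io.write_density_csv(profile, outdir / "density.csv")
    slab_vol = np.diff(profile.edges) * np.prod(np.delete(straj.box, 2))
    report["results"]["density"] = {
        "total_mass_Da": float((profile.density * slab_vol).sum()),
        "expected_mass_Da": float(sum(m for _, _, m in slabs)),
        "peak_density_Da_per_A3": float(profile.density.max()),
    }

    # -- conformer clustering ----------------------------------------------
    cl = cfg["cluster"]
    n_cf = int(cl["n_frames"])
    if n_cf > btraj.n_frames:
        raise PipelineError("cluster", "n_frames exceeds the Brownian trajectory")
    sub = trj.Trajectory(
        coords=btraj.coords[:n_cf], masses=btraj.masses,
        elements=btraj.elements, groups=btraj.groups,
        box=btraj.box, times=btraj.times[:n_cf],
    )
    matrix = trj.rmsd_matrix(sub, "ligand")
    clusters = trj.cluster_frames(matrix, n_clusters=int(cl["n_clusters"]),
                                  seed=seed)
    report["results"]["clusters"] = {
        "n_clusters": clusters.n_clusters,
        "sizes": np.bincount(clusters.labels,
                             minlength=clusters.n_clusters).tolist(),
        "representatives": clusters.representatives.tolist(),
    }

    io.write_json_summary(report, outdir / "report.json")
    return report
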