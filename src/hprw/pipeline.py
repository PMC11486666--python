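"""End-to-end runs: simulate or ingest → metrics → inference → clustering.

A run is fully described by a :class:`RunConfig` (loadable from YAML) with
one global seed; per-stage random streams are derived from it, so changing
e.g. the bootstrap repetition count never perturbs the simulation draws.
Every run writes a manifest echoing the config, per-stage counts that
reconcile (tracks read = analyzed + excluded) and wall-clock timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    TAGS,
    bootstrap_proportions,
    cluster_cells,
    joint_density_contours,
    label_and_merge,
    remove_outliers,
    two_proportion_z_test,
)
from .inference import SpreadKernel, infer_cells, make_grid
from .metrics import FILTER_PRESETS, apply_track_filters, msd_ensemble, track_metrics
from .simulate import PopulationSpec, SimulationConfig, simulate_cohort
from .tracks import AcquisitionSpec, Dialect, TrackTable, read_tracks, write_tracks

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``input_path`` (a track CSV) or ``simulation`` (a
    cohort-generator config) must be set.
    """

    seed: int = 0
    outdir: str = "hprw-run"
    input_path: str | None = None
    simulation: dict | None = None
    dialect: dict | None = None
    frame_interval: float = 0.5
    filter_preset: str = "clustering"
    grid: dict = field(default_factory=dict)  # q_bounds, a_bounds, n_q, n_a
    kernel: dict = field(default_factory=dict)  # half_width_q, half_width_a
    clustering: dict = field(default_factory=dict)  # k, eps, min_pts, n_reps, n_restarts
    max_msd_lag: float = 10.0
    condition_key: str | None = None  # column used for pairwise comparisons

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")
        if self.filter_preset not in FILTER_PRESETS:
            raise ValueError(
                f"unknown filter preset {self.filter_preset!r}; "
                f"choose from {sorted(FILTER_PRESETS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    counts: dict
    timings_s: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, ensure_ascii=False, default=str)


def _build_simulation(sim: dict, seed: int, frame_interval: float) -> SimulationConfig:
    pops = [PopulationSpec(**{**p, "n_steps": tuple(p["n_steps"])
                              if isinstance(p.get("n_steps"), (list, tuple))
                              else p.get("n_steps", 20)})
            for p in sim["populations"]]
    return SimulationConfig(
        populations=pops,
        n_cells=int(sim.get("n_cells", 100)),
        frame_interval=float(sim.get("frame_interval", frame_interval)),
        gap_rate=float(sim.get("gap_rate", 0.0)),
        seed=seed,
        initial_speed_mode=sim.get("initial_speed_mode", "stationary"),
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages and write artifact files under ``config.outdir``.

    Outputs: ``tracks.csv`` (when simulated), ``metrics.csv``, ``msd.csv``,
    ``exclusions.csv``, ``cell_params.csv``, ``cluster_report.json``,
    ``bootstrap.csv``, ``contours.csv``, ``comparisons.csv`` (when two or
    more conditions are present) and ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seed_sim, seed_cluster = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(2)]
    counts: dict = {}
    timings: dict = {}
    warns: list[str] = []

    # --- ingest or simulate ------------------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_config = _build_simulation(config.simulation, seed_sim, config.frame_interval)
        table, truth = simulate_cohort(sim_config)
        write_tracks(table, outdir / "tracks.csv")
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    else:
        dialect = Dialect(**config.dialect) if config.dialect else Dialect()
        acquisition = AcquisitionSpec(frame_interval=config.frame_interval)
        table = read_tracks(config.input_path, dialect, acquisition)
    counts["tracks_read"] = len(table)
    timings["ingest"] = time.perf_counter() - t0

    # --- metrics -----------------------------------------------------------
    t0 = time.perf_counter()
    metrics = track_metrics(table)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    filtered, exclusions = apply_track_filters(table, config.filter_preset)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    counts["tracks_analyzed"] = len(filtered)
    counts["tracks_excluded"] = len(exclusions)
    msd = msd_ensemble(table, max_lag=config.max_msd_lag)
    pd.DataFrame(
        {"lag_min": msd.lags, "msd_um2": msd.msd, "n_tracks": msd.n_tracks}
    ).to_csv(outdir / "msd.csv", index=False)
    timings["metrics"] = time.perf_counter() - t0

    # --- inference ---------------------------------------------------------
    t0 = time.perf_counter()
    grid = make_grid(**config.grid)
    kernel = SpreadKernel(**config.kernel)
    summaries, steps = infer_cells(
        filtered, grid, kernel, policy=config.filter_preset, keep_steps=True
    )
    summaries.to_csv(outdir / "cell_params.csv", index=False)
    steps.to_csv(outdir / "step_params.csv", index=False)
    timings["inference"] = time.perf_counter() - t0

    # --- clustering --------------------------------------------------------
    t0 = time.perf_counter()
    cl = dict(config.clustering)
    k = int(cl.get("k", 4))
    eps = float(cl.get("eps", 0.5))
    min_pts = int(cl.get("min_pts", 5))
    n_reps = int(cl.get("n_reps", 100))
    n_restarts = int(cl.get("n_restarts", 10))
    eligible = summaries[summaries["eligible"]].reset_index(drop=True)
    counts["cells_eligible"] = len(eligible)
    report_dict: dict = {}
    if len(eligible) >= max(k, min_pts):
        inliers = remove_outliers(eligible, eps=eps, min_pts=min_pts)
        counts["cells_outliers"] = int((~inliers).sum())
        report = cluster_cells(
            eligible, k=k, n_restarts=n_restarts, seed=seed_cluster, inlier_mask=inliers
        )
        report = label_and_merge(report)
        boot = bootstrap_proportions(
            eligible, k=k, eps=eps, min_pts=min_pts, n_restarts=n_restarts,
            n_reps=n_reps, seed=seed_cluster,
        )
        if boot.n_redrawn:
            warns.append(f"bootstrap redrew {boot.n_redrawn} degenerate resamples")
        report_dict = {
            "k": k,
            "eps": eps,
            "min_pts": min_pts,
            "seed": seed_cluster,
            "centroids_qa": report.centroids.tolist(),
            "tags": report.tags,
            "proportions": report.proportions,
            "silhouette_by_k": report.silhouette_by_k,
            "n_inliers": int(inliers.sum()),
            "notes": report.notes,
        }
        with open(outdir / "cluster_report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2, ensure_ascii=False)
        pd.DataFrame(
            {
                "tag": list(TAGS),
                "mean_proportion": [boot.mean_proportions[t] for t in TAGS],
                "sd_proportion": [boot.sd_proportions[t] for t in TAGS],
                "mean_cumulative": [boot.mean_cumulative[t] for t in TAGS],
                "sd_cumulative": [boot.sd_cumulative[t] for t in TAGS],
            }
        ).to_csv(outdir / "bootstrap.csv", index=False)
    else:
        warns.append("too few eligible cells for clustering; stage skipped")
        counts["cells_outliers"] = 0

    # contours over per-step estimates
    step_in = steps[steps["track_id"].isin(eligible["track_id"])]
    if len(step_in):
        a_hi = float(grid.a_values[-1])
        cs = joint_density_contours(
            step_in["q_hat"].to_numpy(), step_in["a_hat"].to_numpy(),
            q_domain=(0.0, 1.0), a_domain=(0.0, a_hi),
        )
        qc = 0.5 * (cs.q_edges[:-1] + cs.q_edges[1:])
        ac = 0.5 * (cs.a_edges[:-1] + cs.a_edges[1:])
        qq, aa = np.meshgrid(qc, ac, indexing="ij")
        pd.DataFrame(
            {"q_bin_center": qq.ravel(), "a_bin_center": aa.ravel(), "mass": cs.mass.ravel()}
        ).to_csv(outdir / "contours.csv", index=False)
        with open(outdir / "contour_thresholds.json", "w") as fh:
            json.dump({str(l): cs.thresholds[l] for l in cs.levels}, fh, indent=2)
    timings["clustering"] = time.perf_counter() - t0

    # --- condition comparisons --------------------------------------------
    cond_key = config.condition_key
    if cond_key is None:
        keys = [k_ for k_ in table.condition_keys() if k_ != "population"]
        cond_key = keys[0] if keys else ("population" in table.condition_keys() and "population" or None)
    comp_rows = []
    if cond_key and report_dict and cond_key in eligible.columns:
        inlier_df = eligible[inliers].reset_index(drop=True)
        tags_series = pd.Series(report.cell_tags, index=inlier_df.index)
        conditions = sorted(inlier_df[cond_key].unique())
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                c1, c2 = conditions[i], conditions[j]
                g1 = tags_series[inlier_df[cond_key] == c1]
                g2 = tags_series[inlier_df[cond_key] == c2]
                for tag in TAGS:
                    z, p = two_proportion_z_test(
                        int((g1 == tag).sum()), len(g1), int((g2 == tag).sum()), len(g2)
                    )
                    comp_rows.append(
                        {"condition_1": c1, "condition_2": c2, "tag": tag, "z": z, "p": p}
                    )
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)

    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        counts=counts,
        timings_s={k_: round(v, 3) for k_, v in timings.items()},
        warnings=warns,
    )
    assert counts["tracks_read"] == counts["tracks_analyzed"] + counts["tracks_excluded"]
    manifest.to_json(outdir / "manifest.json")
    return manifest
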