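"""End-to-end orchestration: simulate -> (render/detect) -> track -> MSD ->
fit -> aggregate/coloc -> report, with deterministic seeding.

A single root seed is expanded into per-stage child seeds with
``numpy.random.SeedSequence(root).spawn(...)`` in a fixed stage order
(simulate, render, detect-noise, foci), so any stage can be rerun in
isolation and reproduce its stream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io, msd as msd_mod
from .detect import detect_spots_2d
from .foci import colocalize, count_aggregations
from .models import AcquisitionConfig, GroundTruth, Trajectory
from .simulate import (add_drift, make_nucleus_foci, render_movie,
                       simulate_brownian, simulate_confined, simulate_fbm)
from .track import LinkingParams, drift_correct, filter_trajectories, link_spots

logger = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "render", "detect", "foci")


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(STAGE_NAMES))
    return {name: int(c.generate_state(1)[0]) for name, c in zip(STAGE_NAMES, children)}


def truth_to_trajectories(truth: GroundTruth, nucleus_id: int = 0) -> list[Trajectory]:
    """Wrap ground-truth paths as gap-free trajectories (bypasses detection)."""
    n = truth.n_frames
    frames = np.arange(n)
    return [
        Trajectory(traj_id=i, frames=frames, positions=truth.positions[i, :, :2],
                   n_total_frames=n, dt=truth.dt, nucleus_id=nucleus_id)
        for i in range(truth.n_traj)
    ]


def simulate_group(model: str, n_traj: int, config: AcquisitionConfig, seed: int,
                   **params) -> GroundTruth:
    if model == "brownian":
        return simulate_brownian(n_traj, config, params["D"], seed)
    if model == "fbm":
        return simulate_fbm(n_traj, config, params["D_alpha"], params["alpha"], seed)
    if model == "confined":
        return simulate_confined(n_traj, config, params["A"], params["tau"],
                                 params["D_macro"], seed)
    raise ValueError(f"unknown model {model!r}")


def fit_alphas(trajectories: Sequence[Trajectory], fit_fraction: float = 0.25,
               msd_mode: str = "standard") -> np.ndarray:
    """Per-trajectory anomalous exponents from time-averaged MSDs."""
    alphas = []
    for t in trajectories:
        curve = msd_mod.compute_msd(t, mode=msd_mode)
        alphas.append(msd_mod.fit_anomalous(curve, fit_fraction).alpha)
    return np.asarray(alphas)


def recover_alpha(alpha_true: float, n_traj: int, config: AcquisitionConfig,
                  D_alpha: float = 0.01, seed: int = 0,
                  fit_fraction: float = 0.25) -> np.ndarray:
    """Simulate fBm at a known exponent and return the fitted per-trajectory
    exponents — the parameter-recovery primitive used by ``validate``."""
    truth = simulate_fbm(n_traj, config, D_alpha, alpha_true, seed)
    return fit_alphas(truth_to_trajectories(truth), fit_fraction)


def validate_recovery(alpha_grid: Sequence[float], n_traj: int,
                      config: AcquisitionConfig, D_alpha: float = 0.01,
                      seed: int = 0, fit_fraction: float = 0.25) -> pd.DataFrame:
    """Recovery table: per true exponent, the mean/bias/SE of fitted alpha."""
    rows = []
    columns = ["alpha_true", "n_traj", "alpha_mean", "bias", "alpha_se"]
    if n_traj == 0 or not len(alpha_grid):
        return pd.DataFrame(columns=columns)
    seeds = np.random.SeedSequence(seed).spawn(max(len(alpha_grid), 1))
    for a_true, ss in zip(alpha_grid, seeds):
        alphas = recover_alpha(a_true, n_traj, config, D_alpha,
                               int(ss.generate_state(1)[0]), fit_fraction)
        rows.append({
            "alpha_true": a_true,
            "n_traj": n_traj,
            "alpha_mean": float(alphas.mean()) if len(alphas) else np.nan,
            "bias": float(alphas.mean() - a_true) if len(alphas) else np.nan,
            "alpha_se": (float(alphas.std(ddof=1) / np.sqrt(len(alphas)))
                         if len(alphas) > 1 else np.nan),
        })
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: dict, outdir: Path | str) -> dict:
    """Run the configured stages and write all outputs under ``outdir``.

    Config keys (all optional except ``groups``):
      seed : root seed (default 0)
      acquisition : AcquisitionConfig field overrides
      groups : {name: {model, n_traj, params...}} simulated groups
      render : bool — render movies and re-detect instead of using true paths
      drift : {mode, velocity|amplitude, period} whole-field drift to inject
      linking : LinkingParams field overrides
      fit_fraction, msd_mode : fitting options
      foci : {n_foci, nucleus_radius, aggregate_spec, coloc_spec,
              spot_diameter_nm, coloc_threshold_nm, n_nuclei}

    Returns a summary dict (also written as ``report.json`` / ``report.md``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    seeds = stage_seeds(root_seed)
    acq = AcquisitionConfig(**config.get("acquisition", {}))
    link_params = LinkingParams(**config.get("linking", {}))
    fit_fraction = float(config.get("fit_fraction", 0.25))
    msd_mode = config.get("msd_mode", "standard")
    do_render = bool(config.get("render", False))

    summary: dict = {"seed": root_seed, "groups": {}}
    group_alphas: dict[str, np.ndarray] = {}
    sim_seq = np.random.SeedSequence(seeds["simulate"]).spawn(
        max(len(config.get("groups", {})), 1))
    for gi, (name, gconf) in enumerate(sorted(config.get("groups", {}).items())):
        gseed = int(sim_seq[gi].generate_state(1)[0])
        params = {k: v for k, v in gconf.items() if k not in ("model", "n_traj")}
        truth = simulate_group(gconf["model"], int(gconf["n_traj"]), acq, gseed,
                               **params)
        if "drift" in config:
            truth = add_drift(truth, **config["drift"])
        io.write_csv(io.truth_to_frame(truth), outdir / f"truth_{name}.csv",
                     seed=root_seed, config=config)
        if do_render:
            movie = render_movie(truth, acq, seed=seeds["render"] + gi)
            io.write_movie(movie, outdir / f"movie_{name}.tif")
            spots = []
            for f in range(acq.n_frames):
                spots.extend(detect_spots_2d(
                    movie[f], sigma_px=acq.psf_sigma,
                    threshold=float(config.get("detect_threshold", 5.0)),
                    pixel_size_nm=acq.pixel_size, frame=f))
            io.write_csv(io.spots_to_frame(spots), outdir / f"spots_{name}.csv",
                         seed=root_seed, config=config)
            trajs = link_spots(spots, link_params, n_total_frames=acq.n_frames,
                               dt=acq.dt)
            trajs = filter_trajectories(trajs, link_params)
        else:
            trajs = truth_to_trajectories(truth)
        trajs = drift_correct(trajs)
        io.write_csv(io.trajectories_to_frame(trajs, corrected=True),
                     outdir / f"trajectories_{name}.csv",
                     seed=root_seed, config=config)
        if not trajs:
            logger.warning("group %s: no trajectories survived", name)
            continue
        curves = [msd_mod.compute_msd(t, mode=msd_mode) for t in trajs]
        if len(curves) >= 2:
            ens = msd_mod.ensemble_msd(curves)
            io.write_csv(pd.DataFrame({
                "lag_s": ens.lags, "msd_um2": ens.msd, "se_um2": ens.se,
                "n_traj": ens.n_pairs,
            }), outdir / f"ensemble_msd_{name}.csv", seed=root_seed, config=config)
        alphas = np.asarray([msd_mod.fit_anomalous(c, fit_fraction).alpha
                             for c in curves])
        group_alphas[name] = alphas
        summary["groups"][name] = {
            "n_traj": len(trajs),
            "alpha_mean": float(alphas.mean()),
            "alpha_se": (float(alphas.std(ddof=1) / np.sqrt(len(alphas)))
                         if len(alphas) > 1 else None),
        }

    names = sorted(group_alphas)
    summary["comparisons"] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t_stat, df, p = msd_mod.compare_groups(group_alphas[names[i]],
                                                   group_alphas[names[j]])
            summary["comparisons"][f"{names[i]}_vs_{names[j]}"] = {
                "t": t_stat, "df": df, "p": p}

    if "foci" in config:
        fconf = config["foci"]
        rng_seq = np.random.SeedSequence(seeds["foci"]).spawn(
            int(fconf.get("n_nuclei", 1)))
        agg_rows, coloc_rows = [], []
        for ni, ss in enumerate(rng_seq):
            sample = make_nucleus_foci(
                int(fconf["n_foci"]), float(fconf["nucleus_radius"]),
                fconf.get("aggregate_spec"), fconf.get("coloc_spec"),
                seed=int(ss.generate_state(1)[0]))
            diameter = float(fconf.get("spot_diameter_nm", 200.0))
            agg = count_aggregations(sample.foci_a, diameter, nucleus_id=ni)
            agg_rows.append((ni, agg.n_foci, agg.n_aggregates, agg.threshold_nm))
            if sample.foci_b.size:
                thr = float(fconf.get("coloc_threshold_nm", diameter))
                cr = colocalize(sample.foci_a, sample.foci_b, thr, nucleus_id=ni)
                coloc_rows.append((ni, cr.n_a, cr.n_b, cr.n_coloc, cr.fraction,
                                   cr.threshold_nm))
        io.write_csv(pd.DataFrame(agg_rows, columns=[
            "nucleus_id", "n_foci", "n_aggregates", "threshold_nm"]),
            outdir / "aggregation.csv", seed=root_seed, config=config)
        if coloc_rows:
            io.write_csv(pd.DataFrame(coloc_rows, columns=[
                "nucleus_id", "n_a", "n_b", "n_coloc", "fraction",
                "threshold_nm"]), outdir / "colocalization.csv",
                seed=root_seed, config=config)
        summary["foci"] = {
            "n_nuclei": len(agg_rows),
            "mean_foci": float(np.mean([r[1] for r in agg_rows])),
            "mean_aggregates": float(np.mean([r[2] for r in agg_rows])),
        }
        if coloc_rows:
            summary["foci"]["mean_coloc_fraction"] = float(
                np.mean([r[4] for r in coloc_rows]))

    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_markdown_report(summary, outdir / "report.md")
    return summary


def _write_markdown_report(summary: dict, path: Path) -> None:
    lines = ["# telotrack run report", "", f"seed: {summary['seed']}", ""]
    if summary.get("groups"):
        lines += ["## Groups (mean alpha +/- SE)", ""]
        for name, g in sorted(summary["groups"].items()):
            se = g["alpha_se"]
            se_txt = f" +/- {se:.4f}" if se is not None else ""
            lines.append(f"- {name}: n={g['n_traj']}, "
                         f"alpha = {g['alpha_mean']:.4f}{se_txt}")
        lines.append("")
    if summary.get("comparisons"):
        lines += ["## Group comparisons (Welch two-sided t-test)", ""]
        for name, c in sorted(summary["comparisons"].items()):
            lines.append(f"- {name}: t = {c['t']:.4f}, df = {c['df']:.1f}, "
                         f"p = {c['p']:.3e}")
        lines.append("")
    if summary.get("foci"):
        f = summary["foci"]
        lines += ["## Foci", "",
                  f"- nuclei: {f['n_nuclei']}",
                  f"- mean foci per nucleus: {f['mean_foci']:.2f}",
                  f"- mean aggregates per nucleus: {f['mean_aggregates']:.2f}"]
        if "mean_coloc_fraction" in f:
            lines.append(f"- mean colocalized fraction: "
                         f"{f['mean_coloc_fraction']:.3f}")
        lines.append("")
    path.write_text("\n".join(lines))
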