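"""End-to-end scenario runs: simulate -> normalize -> cluster -> erasure ->
positional, with JSON metrics, logging, and a self-check report.

Each scenario function is pure given (seed, sizes) and returns a flat metrics
dict; :func:`run_pipeline` orchestrates them into a run directory and
:func:`reproduce` compares the headline metrics against the tolerance bands in
``acceptance.yaml``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import spearmanr

from . import __version__
from . import synthetic_data as sd
from .clustering import (classify_course_specificity, cluster6_template,
                         extend_cluster_by_correlation, find_focal_cluster,
                         group_induction_summary, kmeans_profiles,
                         pearson_to_profile)
from .erasure_analysis import (difference_histogram, drop_time,
                               erasure_fraction, panel_erasure_fraction,
                               per_locus_erasure, replication_contribution,
                               sphase_drop, align_by_replication_time)
from .normalization import difference_to_baseline, zero_center_rows
from .positional_analysis import (exclude_confounded, filter_strong_erasure,
                                  running_window_mean)
from .track_io import write_matrix, write_track

log = logging.getLogger("methylerase")

Scenario = Literal["cca", "replication_block", "galdex", "jhd2", "two_course",
                   "study-defaults"]


class RunConfig(BaseModel):
    """Fully serializable run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    scenario: Scenario = "study-defaults"
    seed: int = 0
    out_dir: Optional[str] = None
    n_cluster6: int = 500
    n_background: int = 1500
    horizon_min: float = 90.0
    n_seeds_replication: int = 10
    kinetic_overrides: Dict[str, float] = Field(default_factory=dict)
    write_matrices: bool = True


def _zero_baseline(ids) -> pd.Series:
    """The truth midlog baseline on the measurement scale (log2 ratio 0)."""
    return pd.Series(0.0, index=list(ids))


def _smoothed(row: np.ndarray, window: int = 5) -> np.ndarray:
    return running_window_mean(row, window)


# ---------------------------------------------------------------------------
# scenarios

def scenario_cca(seed: int = 0, n_cluster6: int = 500, n_background: int = 1500,
                 overrides: Optional[Dict[str, float]] = None) -> Dict[str, float]:
    """Default alpha-factor course: clustering recovery, arrest excess,
    one-generation reversion, replication-timing ordering, occupancy anti-phase.
    """
    params = sd.default_params(seed=seed, **(overrides or {}))
    panel, track = sd.make_cluster6_panel(n_cluster6, n_background, seed=seed)
    cond = sd.cca_condition()
    sim = sd.simulate_experiment(panel, params, cond)

    diff = difference_to_baseline(sim.me3, _zero_baseline(sim.me3.ids))

    # clustering: centered profiles -> k-means (k=6) -> correlation extension
    centered = zero_center_rows(sim.me3)
    km = kmeans_profiles(centered, k=6, seed=seed, n_restarts=50)
    template = cluster6_template(centered.times, params.s_phase_window)
    focal = find_focal_cluster(km, template)
    member_idx = [centered.ids.index(rid) for rid in km.members(focal)]
    centroid = centered.values[member_idx].mean(axis=0)
    extended, _ = extend_cluster_by_correlation(centered, centroid, r_min=0.5)
    km.r_min, km.extended_membership = 0.5, extended | set(km.members(focal))

    truth_c6 = set(sim.truth.index[sim.truth["arrest_excess_log2"] > 0])
    background = set(sim.me3.ids) - truth_c6
    membership = km.extended_membership
    recovery = len(membership & truth_c6) / len(truth_c6)
    fpr = len(membership & background) / len(background)

    # arrest-excess summaries (Fig-4C-style, uncentered baseline differences)
    c6_diff = diff.copy_with(
        ids=[rid for rid in diff.ids if rid in truth_c6],
        values=diff.values[[i for i, rid in enumerate(diff.ids) if rid in truth_c6]])
    hist0 = difference_histogram(c6_diff, time_point=0.0)
    hist_gen = difference_histogram(c6_diff, time_point=params.cycle_length_min)
    d0 = diff.values[:, 0]
    member_mask = np.array([rid in membership for rid in diff.ids])
    arrest_excess_percent = float(
        np.mean(100.0 * (2.0 ** d0[member_mask] - 1.0)))

    # replication-timing ordering of the S-phase drop (smoothed series)
    c6_ids = [rid for rid in diff.ids if rid in truth_c6]
    rep_truth = sim.truth.loc[c6_ids, "replication_time_min"].to_numpy()
    dts = np.array([
        drop_time(_smoothed(diff.row(rid)), diff.times, sustain=2)
        for rid in c6_ids])
    ok = np.isfinite(dts)
    rho = float(spearmanr(rep_truth[ok], dts[ok]).statistic)

    # occupancy / H3K4me3 anti-phase across replication-timing extremes
    bins = [(0.0, 0.1), (0.9, 1.0)]
    _, occ_bins, _ = align_by_replication_time(sim.occupancy, track, bins)
    _, me3_bins, _ = align_by_replication_time(sim.me3, track, bins)
    lo, hi = params.s_phase_window
    s_cols = (sim.me3.times >= lo) & (sim.me3.times <= hi)
    occ_gap = float((occ_bins.iloc[0] - occ_bins.iloc[1])[s_cols].mean())
    me3_gap = float((me3_bins.iloc[0] - me3_bins.iloc[1])[s_cols].mean())

    drop_log2, drop_fold = sphase_drop(
        np.nanmean(c6_diff.values, axis=0), c6_diff.times,
        (params.s_phase_window[0], params.s_phase_window[1]))

    return {
        "cluster_recovery": recovery,
        "cluster_false_positive_rate": fpr,
        "n_extended_membership": len(membership),
        "arrest_center_log2": hist0.center,
        "one_generation_center_log2": hist_gen.center,
        "arrest_excess_percent": arrest_excess_percent,
        "drop_time_spearman": rho,
        "mean_sphase_drop_log2": drop_log2,
        "mean_sphase_drop_fold": drop_fold,
        "occupancy_earliest_minus_latest_s": occ_gap,
        "me3_earliest_minus_latest_s": me3_gap,
    }


def scenario_replication_block(seed: int = 0, n_loci: int = 500,
                               horizon: float = 90.0, n_seeds: int = 10,
                               overrides: Optional[Dict[str, float]] = None
                               ) -> Dict[str, float]:
    """Paired replicating / replication-blocked panels (cdc7ts-style release),
    residual erasure ratio and replication contribution at the horizon."""
    residuals, decreases, medians = [], [], []
    for i in range(n_seeds):
        s = int(seed) + i
        params = sd.default_params(seed=s, **(overrides or {}))
        panel, _ = sd.make_cluster6_panel(n_loci, 0, seed=s)
        out = {}
        for name, rep in (("perm", True), ("restr", False)):
            cond = sd.cca_condition(name=f"cdc7_{name}", replication_enabled=rep)
            sim = sd.simulate_experiment(panel, params, cond)
            out[name] = difference_to_baseline(sim.me3, _zero_baseline(sim.me3.ids))
        e_rep = panel_erasure_fraction(out["perm"], horizon)
        e_norep = panel_erasure_fraction(out["restr"], horizon)
        contrib = replication_contribution(e_rep, e_norep)
        residuals.append(contrib.residual_ratio_percent)
        decreases.append(contrib.percent_decrease)
        locus_rep = per_locus_erasure(out["perm"], horizon)
        locus_norep = per_locus_erasure(out["restr"], horizon)
        ratio = (locus_norep / locus_rep).replace([np.inf, -np.inf], np.nan)
        medians.append(float(100.0 * ratio.dropna().median()))
    return {
        "residual_ratio_percent": float(np.mean(residuals)),
        "replication_contribution_percent": float(np.mean(decreases)),
        "residual_ratio_percent_sd": float(np.std(residuals)),
        "per_locus_median_residual_percent": float(np.mean(medians)),
        "n_seeds": n_seeds,
    }


def scenario_galdex(seed: int = 0, horizon: float = 75.0,
                    overrides: Optional[Dict[str, float]] = None
                    ) -> Dict[str, float]:
    """Galactose shutoff with and without cell-cycle release: confounder
    exclusion, strong-erasure filter, and 5' vs 3' release dependence."""
    params = sd.default_params(seed=seed, **(overrides or {}))
    panel, track = sd.make_galdex_panel(seed=seed)
    release = sd.simulate_experiment(panel, params,
                                     sd.galdex_condition("galdex_release", True))
    hold = sd.simulate_experiment(panel, params,
                                  sd.galdex_condition("galdex_hold", False))
    d_rel = difference_to_baseline(release.me3, _zero_baseline(release.me3.ids))
    d_hold = difference_to_baseline(hold.me3, _zero_baseline(hold.me3.ids))

    # alpha+galactose arrest vs midlog+galactose: remove alpha-confounded probes
    rng = np.random.default_rng([int(seed), 0x6d69646c])  # midlog+gal channel noise
    truth = release.truth
    midlog_gal = pd.Series(
        np.where(truth["induction_class"] == "galactose",
                 truth["arrest_excess_log2"], 0.0)
        + rng.normal(0, params.noise_sigma_log2, len(truth)),
        index=truth.index)
    arrest_vals = pd.Series(d_rel.values[:, 0], index=d_rel.ids)
    kept, confound_report = exclude_confounded(arrest_vals, midlog_gal, 0.75)

    n_alpha_total = int((truth["induction_class"] == "alpha").sum())
    removed_alpha = sum(1 for rid in confound_report.removed
                        if truth.loc[rid, "induction_class"] == "alpha")

    strong, strong_report = filter_strong_erasure(d_rel, 0.0, horizon, 75.0)
    strong &= kept

    # release dependence of the log2-excess erasure, 5' vs 3' galactose probes
    gal = truth.index[truth["induction_class"] == "galactose"]
    gal = [rid for rid in gal if rid in kept]
    e_by_arm = {}
    for label, dm in (("release", d_rel), ("hold", d_hold)):
        e_by_arm[label] = {
            rid: erasure_fraction(dm.row(rid), dm.times, horizon,
                                  arrest_value=truth.loc[rid, "arrest_excess_log2"])
            for rid in gal}
    tss = truth["tss_distance_bp"]
    five = [rid for rid in gal if tss[rid] <= params.five_prime_cutoff_bp]
    three = [rid for rid in gal if tss[rid] > params.five_prime_cutoff_bp]

    def mean_e(arm: str, ids: List[str]) -> float:
        return float(np.nanmean([e_by_arm[arm][rid] for rid in ids]))

    ratio5 = mean_e("hold", five) / mean_e("release", five)
    ratio3 = mean_e("hold", three) / mean_e("release", three)
    return {
        "n_confounded_removed": len(confound_report.removed),
        "alpha_confounders_removed_frac": removed_alpha / max(n_alpha_total, 1),
        "n_strong_erasure": len(strong),
        "strong_erasure_five_prime_frac": float(np.mean(
            [tss[rid] <= params.five_prime_cutoff_bp for rid in strong]))
        if strong else float("nan"),
        "five_prime_hold_over_release": float(ratio5),
        "three_prime_hold_over_release": float(ratio3),
    }


def scenario_jhd2(seed: int = 0, horizon: float = 60.0,
                  overrides: Optional[Dict[str, float]] = None
                  ) -> Dict[str, float]:
    """Wild type vs jhd2-deletion release: running-window erasure curves
    ordered by arrest hypermethylation."""
    params = sd.default_params(seed=seed, **(overrides or {}))
    panel, _ = sd.make_cluster6_panel(300, 300, seed=seed)
    wt = sd.simulate_experiment(panel, params, sd.cca_condition("CCA_wt"))
    mut = sd.simulate_experiment(
        panel, params,
        sd.cca_condition("CCA_jhd2", kdem_multiplier=params.jhd2_scale))
    d_wt = difference_to_baseline(wt.me3, _zero_baseline(wt.me3.ids))
    d_mut = difference_to_baseline(mut.me3, _zero_baseline(mut.me3.ids))

    # erasure (positive = loss) at the horizon, ordered by arrest hypermethylation
    order = np.argsort(-d_wt.values[:, 0])
    t_idx = int(np.argmin(np.abs(d_wt.times - horizon)))
    erase_wt = (d_wt.values[:, 0] - d_wt.values[:, t_idx])[order]
    erase_mut = (d_mut.values[:, 0] - d_mut.values[:, t_idx])[order]
    w_wt = running_window_mean(erase_wt, 50)
    w_mut = running_window_mean(erase_mut, 50)
    # restrict to hypermethylated probes (the erasure-cluster half)
    top = slice(0, int(len(order) * 0.4))
    return {
        "windowed_erasure_wt_minus_jhd2": float(np.mean(w_wt[top] - w_mut[top])),
        "frac_windows_wt_geq_jhd2": float(np.mean(w_wt[top] >= w_mut[top])),
    }


def scenario_two_course(seed: int = 0,
                        overrides: Optional[Dict[str, float]] = None
                        ) -> Dict[str, float]:
    """Shared panel under both synchrony protocols: concatenated clustering,
    per-course extension, course-specificity labels, induction summaries."""
    panels, track = sd.make_two_course_panel(seed=seed)
    p_cca = sd.default_params(seed=seed, **(overrides or {}))
    p_ccts = sd.ccts_params(seed=seed, **(overrides or {}))
    sim_a = sd.simulate_experiment(panels["CCA"], p_cca, sd.cca_condition())
    sim_ts = sd.simulate_experiment(panels["CCTS"], p_ccts, sd.ccts_condition())

    from .normalization import concatenate_courses
    cat = concatenate_courses(zero_center_rows(sim_a.me3),
                              zero_center_rows(sim_ts.me3))
    km = kmeans_profiles(cat, k=6, seed=seed, n_restarts=50)
    n_a = len(sim_a.me3.times)
    seg_cols = {"CCA": slice(0, n_a), "CCTS": slice(n_a, len(cat.times))}
    s_windows = {"CCA": p_cca.s_phase_window, "CCTS": p_ccts.s_phase_window}

    r_by_course, members_by_course = {}, {}
    for course, sim in (("CCA", sim_a), ("CCTS", sim_ts)):
        cols = seg_cols[course]
        template = cluster6_template(sim.me3.times, s_windows[course])
        focal = find_focal_cluster(km, template, cols)
        idx = [cat.ids.index(rid) for rid in km.members(focal)]
        centroid = cat.values[idx][:, cols].mean(axis=0)
        r, _ = pearson_to_profile(cat, centroid, cols)
        r_by_course[course] = r
        members_by_course[course] = set(r.index[r >= 0.5]) | set(km.members(focal))

    membership = members_by_course["CCA"] | members_by_course["CCTS"]
    truth_classes = sim_a.truth["induction_class"]
    erasure_ids = set(truth_classes.index[truth_classes.isin(["alpha", "heat"])])
    background = set(cat.ids) - erasure_ids
    recovery = len(membership & erasure_ids) / len(erasure_ids)
    fpr = len(membership & background) / len(background)

    labels, _ = classify_course_specificity(
        r_by_course["CCA"].reindex(sorted(membership)),
        r_by_course["CCTS"].reindex(sorted(membership)), margin=0.2)
    heat_ids = [rid for rid in labels.index if truth_classes.get(rid) == "heat"]
    frac_heat_ts = float((labels.loc[heat_ids] == "TS>A").mean()) if heat_ids \
        else float("nan")

    heat_induction = track.annotation("heat_induction_log2")
    summary = group_induction_summary(labels.to_dict(), heat_induction.to_dict())
    mean_heat_ts = float(summary.loc["TS>A", "mean"]) if "TS>A" in summary.index \
        else float("nan")
    mean_heat_a = float(summary.loc["A>TS", "mean"]) if "A>TS" in summary.index \
        else float("nan")
    return {
        "two_course_recovery": recovery,
        "two_course_false_positive_rate": fpr,
        "frac_heat_labelled_ts": frac_heat_ts,
        "mean_heat_induction_ts_gt_a": mean_heat_ts,
        "mean_heat_induction_a_gt_ts": mean_heat_a,
    }


def dilution_fold_check(seed: int = 0) -> float:
    """Fold drop across a single replication event in the dilution-only model
    (k_dep = k_dem = 0, no noise): exactly the two-fold ceiling."""
    params = sd.default_params(seed=seed, k_dem=0.0, noise_sigma_log2=0.0)
    locus = sd.LocusSpec(nucleosome_id="dilution_only", replication_time_min=10.0,
                         tss_distance_bp=100.0, induction_class="alpha",
                         arrest_excess_log2=0.5, baseline_fraction=0.3)
    cond = sd.cca_condition()
    m = sd.methylation_trajectory(locus, params, cond)
    grid = np.asarray(cond.time_grid_min)
    before = m[grid < 10.0][-1]
    after = m[grid >= 10.0][0]
    return float(before / after)


SCENARIOS = {
    "cca": scenario_cca,
    "replication_block": scenario_replication_block,
    "galdex": scenario_galdex,
    "jhd2": scenario_jhd2,
    "two_course": scenario_two_course,
}


# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Tuple[Dict[str, Dict[str, float]], Optional[Path]]:
    """Execute the configured scenario(s); write metrics JSON, artifacts and a
    log into the run directory (if configured).  Any stage error aborts with
    the stage named."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    names = list(SCENARIOS) if config.scenario == "study-defaults" \
        else [config.scenario]
    metrics: Dict[str, Dict[str, float]] = {}
    timings: Dict[str, float] = {}
    overrides = dict(config.kinetic_overrides)
    for name in names:
        t0 = time.perf_counter()
        try:
            if name == "cca":
                metrics[name] = scenario_cca(config.seed, config.n_cluster6,
                                             config.n_background, overrides)
            elif name == "replication_block":
                metrics[name] = scenario_replication_block(
                    config.seed, config.n_cluster6, config.horizon_min,
                    config.n_seeds_replication, overrides)
            else:
                metrics[name] = SCENARIOS[name](config.seed, overrides=overrides)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, timings[name])
    metrics["checks"] = {"dilution_fold": dilution_fold_check(config.seed)}

    if out_dir:
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        resolved = config.model_dump()
        (out_dir / "run_log.json").write_text(json.dumps({
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "resolved_config": resolved,
            "stage_seconds": timings,
        }, indent=2))
        if config.write_matrices and config.scenario in ("cca", "study-defaults"):
            params = sd.default_params(seed=config.seed,
                                       **config.kinetic_overrides)
            panel, track = sd.make_cluster6_panel(
                config.n_cluster6, config.n_background, seed=config.seed)
            sim = sd.simulate_experiment(panel, params, sd.cca_condition())
            write_matrix(sim.me3, out_dir / "cca_me3.tsv")
            write_matrix(sim.occupancy, out_dir / "cca_occupancy.tsv")
            write_track(track, out_dir / "cca_track.tsv")
            sim.truth.to_csv(out_dir / "cca_truth.tsv", sep="\t", na_rep="NA")
    return metrics, out_dir


def _load_tolerances() -> dict:
    path = Path(__file__).with_name("acceptance.yaml")
    return yaml.safe_load(path.read_text())


def reproduce(seed: int = 0, kinetic_overrides: Optional[Dict[str, float]] = None
              ) -> pd.DataFrame:
    """Run the headline scenarios and report measured value vs tolerance band.

    Failures are reported in the table, not raised.
    """
    overrides = kinetic_overrides or {}
    tol = _load_tolerances()
    rb = scenario_replication_block(seed=seed, overrides=overrides)
    cca = scenario_cca(seed=seed, overrides=overrides)
    measured = {
        "dilution_fold": dilution_fold_check(seed),
        "residual_ratio_percent": rb["residual_ratio_percent"],
        "replication_contribution_percent": rb["replication_contribution_percent"],
        "arrest_center_log2": cca["arrest_center_log2"],
        "arrest_excess_percent": cca["arrest_excess_percent"],
    }
    rows = []
    for name, spec in tol["targets"].items():
        value = measured[name]
        lo, hi = spec["low"], spec["high"]
        rows.append({"target": name, "value": value, "low": lo, "high": hi,
                     "pass": bool(lo <= value <= hi)})
    return pd.DataFrame(rows).set_index("target")
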