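"""Mechanistic generator for per-nucleosome H3K4me3 time courses.

Each locus carries a methylated fraction ``M(t)`` evolving under
transcription-coupled deposition, first-order enzymatic demethylation, and an
instantaneous two-fold dilution when the replication fork passes (see
:mod:`methylerase.params` for the model statement).  Trajectories are solved
exactly with the piecewise closed form

    M(t) = M_ss + (M(t0) - M_ss) * exp(-kappa * (t - t0))

between events, so there is no integration error to tune.

Measurements emulate tiling-array log-ratios: ``log2(M / baseline) + noise``
for the H3K4me3 channel, and ``log2(copies / panel-mean copies) + noise`` for
the nucleosome occupancy channel (copy number doubles when a locus has
replicated).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, DegenerateLocusError
from .params import ConditionSpec, KineticParams, LocusSpec
from .track_io import NucleosomeTrack, TimeCourseMatrix, TRACK_COLUMNS

__all__ = [
    "methylation_trajectory",
    "measure",
    "occupancy_trajectory",
    "simulate_experiment",
    "calibrate_demethylation_rate",
    "default_params",
    "cca_condition",
    "ccts_condition",
    "galdex_condition",
    "make_cluster6_panel",
    "make_two_course_panel",
    "make_galdex_panel",
    "SimulationResult",
]

DEFAULT_GRID = tuple(float(t) for t in range(0, 95, 5))


# ---------------------------------------------------------------------------
# kinetics

def _effective_k_dem(locus: LocusSpec, params: KineticParams,
                     condition: ConditionSpec) -> float:
    positional = 1.0 if locus.tss_distance_bp <= params.five_prime_cutoff_bp \
        else params.three_prime_dem_scale
    return params.k_dem * condition.kdem_multiplier * locus.k_dem_scale * positional


def _advance(m: float, dt: float, k_dep: float, k_dem: float,
             k_remeth: float) -> float:
    """Closed-form relaxation over an event-free interval of length ``dt``."""
    s = k_dep + k_dem
    if s <= 0.0:
        return m
    m_ss = k_dep / s
    kappa = s + (k_remeth if m < m_ss else 0.0)
    return m_ss + (m - m_ss) * np.exp(-kappa * dt)


def methylation_trajectory(locus: LocusSpec, params: KineticParams,
                           condition: ConditionSpec) -> np.ndarray:
    """Methylated fraction ``M`` sampled on ``condition.time_grid_min``.

    ``M(0)`` is the arrest-phase level: ``baseline * 2**arrest_excess_log2``
    when the locus's induction class matches the condition's arrest stimulus,
    else the midlog baseline.  A sample taken exactly at the replication time
    sees the post-dilution value.
    """
    grid = np.asarray(condition.time_grid_min, dtype=float)
    b = locus.baseline_fraction
    k_dem_eff = _effective_k_dem(locus, params, condition)
    induced = locus.induction_class in condition.effective_arrest_classes
    m = min(b * 2.0 ** (locus.arrest_excess_log2 if induced else 0.0), 1.0)

    if locus.induction_class in condition.sustained_classes:
        # the inducing stimulus persists: the arrest-phase steady state is held
        out = np.full_like(grid, m)
        if condition.replication_enabled:
            out[grid >= locus.replication_time_min] /= params.dilution_factor
        return out

    rep_t = locus.replication_time_min if condition.replication_enabled else None
    onset = params.demethylation_onset_min

    def rates(t0: float, stimulus_on: bool) -> Tuple[float, float]:
        dem = k_dem_eff if t0 >= onset else 0.0
        if stimulus_on:
            dep = params.k_dep_induced
        elif params.tie_deposition_to_baseline:
            dep = dem * b / (1.0 - b)
        else:
            dep = params.k_dep_mid
        return dep, dem

    out = np.empty_like(grid)
    t_prev = grid[0]
    if rep_t is not None and rep_t <= t_prev:
        m /= params.dilution_factor
        rep_t = None
    out[0] = m
    for j in range(1, len(grid)):
        t_next = grid[j]
        # split the grid interval at internal breakpoints (demethylation onset,
        # replication event); stimulus is piecewise-constant per grid interval
        stimulus_on = condition.stimulus_active(t_prev)
        cuts = [t_next]
        if t_prev < onset < t_next:
            cuts.append(onset)
        if rep_t is not None and t_prev < rep_t <= t_next:
            cuts.append(rep_t)
        t0 = t_prev
        for t1 in sorted(set(cuts)):
            dep, dem = rates(t0, stimulus_on)
            m = _advance(m, t1 - t0, dep, dem, params.k_remeth)
            if rep_t is not None and t1 == rep_t:
                m /= params.dilution_factor
                rep_t = None
            t0 = t1
        out[j] = m
        t_prev = t_next
    # the closed form cannot leave [0, 1]; clip defensively against rounding
    return np.clip(out, 0.0, 1.0)


#: fixed mid-probability quadrature for the synchrony-dispersion average
_JITTER_QUANTILES = 9


def population_trajectory(locus: LocusSpec, params: KineticParams,
                          condition: ConditionSpec) -> np.ndarray:
    """Methylated fraction averaged over population synchrony dispersion.

    The measured channel sees a culture whose cells replicate a locus at
    ``replication_time_min`` jittered by ``N(0, sync_sd_min^2)``; the average
    is taken by deterministic mid-probability quadrature over that jitter.
    Reduces to :func:`methylation_trajectory` when dispersion is zero or
    replication is disabled.
    """
    from scipy.stats import norm

    if params.sync_sd_min == 0 or not condition.replication_enabled:
        return methylation_trajectory(locus, params, condition)
    probs = (np.arange(_JITTER_QUANTILES) + 0.5) / _JITTER_QUANTILES
    taus = locus.replication_time_min + params.sync_sd_min * norm.ppf(probs)
    acc = np.zeros(len(condition.time_grid_min))
    for tau in taus:
        jittered = locus.model_copy(
            update={"replication_time_min": max(float(tau), 0.0)})
        acc += methylation_trajectory(jittered, params, condition)
    return acc / _JITTER_QUANTILES


def measure(m: np.ndarray, baseline_fraction: float, noise_sigma_log2: float,
            seed) -> np.ndarray:
    """Array-style log2 enrichment: ``log2(M / baseline) + N(0, sigma)``.

    ``seed`` may be an int or any value accepted by
    :func:`numpy.random.default_rng`; the draw is deterministic given it.
    """
    m = np.asarray(m, dtype=float)
    if baseline_fraction <= 0:
        raise DegenerateLocusError("baseline_fraction must be > 0")
    if np.any(m <= 0):
        raise DegenerateLocusError("M reached 0; log-ratio undefined for this locus")
    signal = np.log2(m / baseline_fraction)
    if noise_sigma_log2 == 0:
        return signal
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, noise_sigma_log2, size=m.shape)


def _copies(panel: Sequence[LocusSpec], condition: ConditionSpec,
            sync_sd_min: float = 0.0) -> np.ndarray:
    from scipy.stats import norm

    grid = np.asarray(condition.time_grid_min, dtype=float)
    c = np.ones((len(panel), len(grid)))
    if condition.replication_enabled:
        for i, locus in enumerate(panel):
            if sync_sd_min > 0:
                c[i] = 1.0 + norm.cdf(
                    (grid - locus.replication_time_min) / sync_sd_min)
            else:
                c[i, grid >= locus.replication_time_min] = 2.0
    return c


def occupancy_trajectory(panel: Sequence[LocusSpec], condition: ConditionSpec,
                         sync_sd_min: float = 0.0) -> np.ndarray:
    """Relative occupancy ``log2(c_i(t) / <c(t)>)`` for every locus in the panel.

    Copy number is 1 before a locus replicates and 2 after (1 throughout when
    replication is disabled; a step smoothed by the population synchrony
    dispersion when ``sync_sd_min > 0``); ``<c(t)>`` is the panel mean at
    ``t``, so the panel mean of ``2**signal`` is exactly 1 at every time point.
    """
    if len(panel) == 0:
        raise ValueError("occupancy_trajectory: empty panel")
    c = _copies(panel, condition, sync_sd_min)
    return np.log2(c / c.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# experiment-level simulation

def _locus_seed(root: int, nucleosome_id: str, condition: str, channel: str):
    """Stable per-(locus, condition, channel) seed sequence.

    Uses CRC32 of the id so that subsetting or reordering a panel never
    perturbs another locus's noise stream.
    """
    return [int(root),
            zlib.crc32(nucleosome_id.encode()),
            zlib.crc32(condition.encode()),
            zlib.crc32(channel.encode())]


@dataclass
class SimulationResult:
    """Measured channels plus the hidden truth used by recovery tests."""

    me3: TimeCourseMatrix
    occupancy: TimeCourseMatrix
    midlog: pd.Series              # one noisy midlog log2 measurement per locus
    truth: pd.DataFrame            # per-locus effective parameters
    truth_m: pd.DataFrame          # noiseless methylated fractions
    condition: ConditionSpec


def simulate_experiment(panel: Sequence[LocusSpec], params: KineticParams,
                        condition: ConditionSpec) -> SimulationResult:
    """Simulate one experimental arm for a panel of loci.

    Deterministic given ``params.seed``: identical inputs give bit-identical
    matrices.  Raises on duplicate nucleosome ids.
    """
    ids = [l.nucleosome_id for l in panel]
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)
        raise ValueError(f"duplicate nucleosome_id in panel: "
                         f"{sorted(set(dup[dup.duplicated()]))[:5]}")
    if not panel:
        raise ValueError("empty panel")
    grid = np.asarray(condition.time_grid_min, dtype=float)

    m_rows, sig_rows, mid_vals = [], [], []
    truth_rows = []
    for locus in panel:
        m = population_trajectory(locus, params, condition)
        sig = measure(m, locus.baseline_fraction, params.noise_sigma_log2,
                      _locus_seed(params.seed, locus.nucleosome_id,
                                  condition.name, "H3K4me3"))
        mid = measure(np.array([locus.baseline_fraction]), locus.baseline_fraction,
                      params.noise_sigma_log2,
                      _locus_seed(params.seed, locus.nucleosome_id,
                                  "midlog", "H3K4me3"))[0]
        induced = locus.induction_class in condition.effective_arrest_classes
        truth_rows.append({
            "nucleosome_id": locus.nucleosome_id,
            "baseline_fraction": locus.baseline_fraction,
            "arrest_excess_log2": locus.arrest_excess_log2 if induced else 0.0,
            "replication_time_min": locus.replication_time_min,
            "replicated": bool(condition.replication_enabled),
            "k_dem_eff": _effective_k_dem(locus, params, condition),
            "tss_distance_bp": locus.tss_distance_bp,
            "induction_class": locus.induction_class,
        })
        m_rows.append(m)
        sig_rows.append(sig)
        mid_vals.append(mid)

    occ = occupancy_trajectory(panel, condition, params.sync_sd_min)
    if params.noise_sigma_log2 > 0:
        occ = occ + np.vstack([
            np.random.default_rng(
                _locus_seed(params.seed, l.nucleosome_id, condition.name, "occupancy")
            ).normal(0.0, params.noise_sigma_log2, size=len(grid))
            for l in panel
        ])

    me3 = TimeCourseMatrix(ids=ids, times=grid, values=np.vstack(sig_rows),
                           condition=condition.name, channel="H3K4me3")
    occm = TimeCourseMatrix(ids=ids, times=grid, values=occ,
                            condition=condition.name, channel="occupancy")
    truth = pd.DataFrame(truth_rows).set_index("nucleosome_id")
    truth_m = pd.DataFrame(np.vstack(m_rows), index=pd.Index(ids, name="nucleosome_id"),
                           columns=grid)
    return SimulationResult(me3=me3, occupancy=occm,
                            midlog=pd.Series(mid_vals, index=ids, name="midlog"),
                            truth=truth, truth_m=truth_m, condition=condition)


# ---------------------------------------------------------------------------
# calibration

def _noiseless_erasure(locus: LocusSpec, params: KineticParams,
                       condition: ConditionSpec, horizon: float) -> float:
    """Erasure fraction of the log2 excess at ``horizon`` on the noiseless path."""
    m = methylation_trajectory(locus, params, condition)
    grid = np.asarray(condition.time_grid_min, dtype=float)
    d = np.log2(m / locus.baseline_fraction)
    d_h = float(np.interp(horizon, grid, d))
    e0 = d[0]
    if e0 <= 0:
        raise CalibrationError("reference locus has no arrest excess")
    return (e0 - d_h) / e0


def calibrate_demethylation_rate(
    target_residual_ratio: float,
    horizon_min: float,
    params: KineticParams,
    reference: LocusSpec,
    condition_rep: Optional[ConditionSpec] = None,
    condition_norep: Optional[ConditionSpec] = None,
    bracket: Tuple[float, float] = (1e-6, 2.0),
) -> float:
    """Find ``k_dem`` so that erasure without replication is the requested
    fraction of erasure with replication at ``horizon_min``.

    Solved by root-bracketed bisection on noiseless trajectories of the
    reference locus.  A target of 1.0 is non-identifiable (both arms complete)
    and raises; so does a bracket that does not straddle the target.
    """
    if not 0.0 < target_residual_ratio < 1.0:
        raise CalibrationError(
            f"target_residual_ratio must be in (0, 1); {target_residual_ratio} "
            "is non-identifiable (any sufficiently large k_dem satisfies 1.0)"
        )
    if condition_rep is None:
        condition_rep = cca_condition()
    if condition_norep is None:
        condition_norep = condition_rep.model_copy(
            update={"name": condition_rep.name + "_norep",
                    "replication_enabled": False})
    grid = condition_rep.time_grid_min
    if not (grid[0] <= horizon_min <= grid[-1]):
        raise CalibrationError(f"horizon {horizon_min} outside grid {grid[0]}..{grid[-1]}")

    def residual(k: float) -> float:
        p = params.model_copy(update={"k_dem": k})
        e_rep = _noiseless_erasure(reference, p, condition_rep, horizon_min)
        e_norep = _noiseless_erasure(reference, p, condition_norep, horizon_min)
        if e_rep <= 0:
            raise CalibrationError("replication-enabled erasure is <= 0; "
                                   "target unattainable for this reference locus")
        return e_norep / e_rep

    lo, hi = bracket
    f_lo = residual(lo) - target_residual_ratio
    f_hi = residual(hi) - target_residual_ratio
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"bisection bracket {bracket} does not straddle target "
            f"{target_residual_ratio} (residuals {f_lo + target_residual_ratio:.4f}, "
            f"{f_hi + target_residual_ratio:.4f})"
        )
    return float(brentq(lambda k: residual(k) - target_residual_ratio, lo, hi,
                        xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# default study conditions

#: documented default: residual (non-replicating / replicating) erasure ratio
#: the demethylation rate is calibrated to, at this horizon
DEFAULT_RESIDUAL_TARGET = 0.75
DEFAULT_CALIBRATION_HORIZON = 90.0

_DEFAULT_KDEM_CACHE: Dict[Tuple[float, float], float] = {}


def _reference_locus() -> LocusSpec:
    """Mid-S-phase 5' locus used for rate calibration (CCA S window midpoint)."""
    return LocusSpec(nucleosome_id="__calibration_ref__", replication_time_min=22.5,
                     tss_distance_bp=200.0, induction_class="alpha",
                     arrest_excess_log2=0.5, baseline_fraction=0.3)


def default_params(seed: int = 0, **overrides) -> KineticParams:
    """Study-default kinetic parameters.

    ``k_dem`` is derived at call time by calibrating the residual erasure
    ratio to :data:`DEFAULT_RESIDUAL_TARGET` at 90 min on the reference locus
    (it is a derived quantity, not a hand-set constant).  Any field can be
    overridden.
    """
    key = (DEFAULT_RESIDUAL_TARGET, DEFAULT_CALIBRATION_HORIZON)
    if key not in _DEFAULT_KDEM_CACHE:
        base = KineticParams(k_dem=0.01, noise_sigma_log2=0.0, seed=0)
        _DEFAULT_KDEM_CACHE[key] = calibrate_demethylation_rate(
            DEFAULT_RESIDUAL_TARGET, DEFAULT_CALIBRATION_HORIZON, base,
            _reference_locus())
    kw = {"k_dem": _DEFAULT_KDEM_CACHE[key], "seed": seed}
    kw.update(overrides)
    return KineticParams(**kw)


def cca_condition(name: str = "CCA", replication_enabled: bool = True,
                  kdem_multiplier: float = 1.0,
                  grid: Sequence[float] = DEFAULT_GRID) -> ConditionSpec:
    """Alpha-factor arrest/release; S phase ~10-35 min, 60 min cycle."""
    return ConditionSpec(name=name, protocol="CCA",
                         replication_enabled=replication_enabled,
                         kdem_multiplier=kdem_multiplier,
                         time_grid_min=tuple(grid))


def ccts_condition(name: str = "CCTS", replication_enabled: bool = True,
                   kdem_multiplier: float = 1.0,
                   grid: Sequence[float] = DEFAULT_GRID) -> ConditionSpec:
    """cdc28-13 temperature-shift arrest/release; S phase ~30-70 min, 90 min cycle."""
    return ConditionSpec(name=name, protocol="CCTS",
                         replication_enabled=replication_enabled,
                         kdem_multiplier=kdem_multiplier,
                         time_grid_min=tuple(grid))


def galdex_condition(name: str = "galdex_release", replication_enabled: bool = True,
                     grid: Sequence[float] = tuple(float(t) for t in range(0, 80, 5))
                     ) -> ConditionSpec:
    """Galactose-to-dextrose shift after alpha-factor + galactose arrest.

    ``replication_enabled=False`` models the arm held in alpha factor: no cell
    cycle re-entry, and the alpha-induced arrest state persists (those loci are
    the confounders the ``log2 > 0.75`` filter removes).
    """
    return ConditionSpec(name=name, protocol="galdex",
                         replication_enabled=replication_enabled,
                         time_grid_min=tuple(grid),
                         arrest_classes=("galactose", "alpha"),
                         sustained_classes=() if replication_enabled else ("alpha",))


def ccts_params(seed: int = 0, **overrides) -> KineticParams:
    """Defaults adjusted for the slower temperature-shift cycle (and its
    poorer synchrony)."""
    kw = dict(cycle_length_min=90.0, s_phase_window=(30.0, 70.0), sync_sd_min=8.0)
    kw.update(overrides)
    return default_params(seed=seed, **kw)


# ---------------------------------------------------------------------------
# panel builders (the study conditions)

_S_WINDOWS = {"CCA": (10.0, 35.0), "CCTS": (30.0, 70.0), "galdex": (10.0, 35.0)}

#: arrest hypermethylation of erasure-cluster loci: log2 excess ~ N(0.5, 0.15^2)
CLUSTER6_EXCESS_MEAN = 0.5
CLUSTER6_EXCESS_SD = 0.15


def _build_track(loci: Sequence[LocusSpec], rng: np.random.Generator,
                 rep_times: Optional[Dict[str, float]] = None) -> NucleosomeTrack:
    rows = []
    for i, l in enumerate(loci):
        heat = float(rng.normal(2.5, 0.5)) if l.induction_class == "heat" \
            else float(rng.normal(0.0, 0.4))
        alpha = float(rng.normal(2.5, 0.5)) if l.induction_class == "alpha" \
            else float(rng.normal(0.0, 0.4))
        start = 200 * i
        rows.append({
            "chrom": "chrSIM",
            "start": start,
            "end": start + 147,
            "nucleosome_id": l.nucleosome_id,
            "replication_time_min": (rep_times or {}).get(
                l.nucleosome_id, l.replication_time_min),
            "tss_distance_bp": l.tss_distance_bp,
            "gene": f"GENE{i // 4:04d}",
            "induction_class": l.induction_class,
            "heat_induction_log2": heat,
            "alpha_induction_log2": alpha,
        })
    return NucleosomeTrack(pd.DataFrame(rows, columns=TRACK_COLUMNS))


def make_cluster6_panel(n_cluster6: int = 500, n_background: int = 1500,
                        seed: int = 0, protocol: str = "CCA",
                        induction_class: str = "alpha"
                        ) -> Tuple[List[LocusSpec], NucleosomeTrack]:
    """Default single-course panel: arrest-induced ("Cluster-6-like") loci with
    log2 excess ~ N(0.5, 0.15^2) plus flat background loci.

    Replication times are uniform over the protocol's S-phase window; induced
    loci sit within 500 bp of a TSS (5' positions), background loci are spread
    5' and 3'.
    """
    rng = np.random.default_rng([int(seed), zlib.crc32(b"panel"),
                                 zlib.crc32(protocol.encode())])
    lo, hi = _S_WINDOWS[protocol]
    loci: List[LocusSpec] = []
    for i in range(n_cluster6):
        e0 = float(np.clip(rng.normal(CLUSTER6_EXCESS_MEAN, CLUSTER6_EXCESS_SD),
                           0.05, 1.5))
        loci.append(LocusSpec(
            nucleosome_id=f"c6_{i:04d}",
            replication_time_min=float(rng.uniform(lo, hi)),
            tss_distance_bp=float(rng.uniform(50, 450)),
            induction_class=induction_class,
            arrest_excess_log2=e0,
            baseline_fraction=0.3,
        ))
    for i in range(n_background):
        loci.append(LocusSpec(
            nucleosome_id=f"bg_{i:04d}",
            replication_time_min=float(rng.uniform(lo, hi)),
            tss_distance_bp=float(rng.uniform(50, 1500)),
            induction_class="none",
            arrest_excess_log2=0.0,
            baseline_fraction=0.3,
        ))
    return loci, _build_track(loci, rng)


def make_two_course_panel(n_alpha: int = 250, n_heat: int = 250,
                          n_background: int = 1500, seed: int = 0
                          ) -> Tuple[Dict[str, List[LocusSpec]], NucleosomeTrack]:
    """Shared panel observed under both synchrony protocols.

    The same nucleosomes replicate at different minutes after release in the
    two protocols (their S phases differ), so the panel is returned as one
    locus list per protocol, sharing ids and replication-order quantiles.
    The track records the CCA replication times.
    """
    rng = np.random.default_rng([int(seed), zlib.crc32(b"two_course")])
    quantiles = {}
    base: List[Tuple[str, str, float, float]] = []  # id, class, excess, tss
    for i in range(n_alpha):
        base.append((f"a6_{i:04d}", "alpha",
                     float(np.clip(rng.normal(0.5, 0.15), 0.05, 1.5)),
                     float(rng.uniform(50, 450))))
    for i in range(n_heat):
        base.append((f"h6_{i:04d}", "heat",
                     float(np.clip(rng.normal(0.5, 0.15), 0.05, 1.5)),
                     float(rng.uniform(50, 450))))
    for i in range(n_background):
        base.append((f"bg_{i:04d}", "none", 0.0, float(rng.uniform(50, 1500))))
    for rid, *_ in base:
        quantiles[rid] = float(rng.uniform(0, 1))

    panels: Dict[str, List[LocusSpec]] = {}
    for protocol in ("CCA", "CCTS"):
        lo, hi = _S_WINDOWS[protocol]
        panels[protocol] = [
            LocusSpec(nucleosome_id=rid, induction_class=cls,
                      arrest_excess_log2=e0, tss_distance_bp=tss,
                      replication_time_min=lo + quantiles[rid] * (hi - lo),
                      baseline_fraction=0.3)
            for rid, cls, e0, tss in base
        ]
    track = _build_track(panels["CCA"], rng)
    return panels, track


def make_galdex_panel(n_gal5: int = 150, n_gal3: int = 150, n_alpha: int = 50,
                      n_background: int = 300, seed: int = 0
                      ) -> Tuple[List[LocusSpec], NucleosomeTrack]:
    """Galactose-shutoff panel: strongly induced GAL-class loci (5' and 3'
    positions), alpha-confounded loci (hypermethylated by the arrest itself and
    removed by the log2>0.75 confounder filter), and background.

    GAL loci carry a 3.5x demethylase-targeting multiplier: erasure of GAL
    methylation without replication is nearly complete by 75 min, faster than
    the genome-average calibrated rate.
    """
    rng = np.random.default_rng([int(seed), zlib.crc32(b"galdex")])
    lo, hi = _S_WINDOWS["galdex"]
    loci: List[LocusSpec] = []

    def gal_locus(rid: str, tss: float) -> LocusSpec:
        return LocusSpec(
            nucleosome_id=rid,
            replication_time_min=float(rng.uniform(lo, hi)),
            tss_distance_bp=tss,
            induction_class="galactose",
            arrest_excess_log2=float(np.clip(rng.normal(2.5, 0.3), 1.5, 3.4)),
            baseline_fraction=0.08,
            k_dem_scale=3.5,
        )

    for i in range(n_gal5):
        loci.append(gal_locus(f"g5_{i:04d}", float(rng.uniform(50, 450))))
    for i in range(n_gal3):
        loci.append(gal_locus(f"g3_{i:04d}", float(rng.uniform(800, 2500))))
    for i in range(n_alpha):
        loci.append(LocusSpec(
            nucleosome_id=f"ac_{i:04d}",
            replication_time_min=float(rng.uniform(lo, hi)),
            tss_distance_bp=float(rng.uniform(50, 450)),
            induction_class="alpha",
            arrest_excess_log2=float(rng.uniform(1.0, 1.6)),
            baseline_fraction=0.3,
        ))
    for i in range(n_background):
        loci.append(LocusSpec(
            nucleosome_id=f"bg_{i:04d}",
            replication_time_min=float(rng.uniform(lo, hi)),
            tss_distance_bp=float(rng.uniform(50, 2500)),
            induction_class="none",
            arrest_excess_log2=0.0,
            baseline_fraction=0.3,
        ))
    return loci, _build_track(loci, rng)
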