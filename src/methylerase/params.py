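"""Domain parameter types for the kinetic simulator.

The generative model is a two-state (methylated / unmethylated) description of
each nucleosome position.  Between discrete events the methylated fraction
``M`` relaxes exponentially toward the steady state set by transcription-coupled
deposition (rate ``k_dep``) and enzymatic demethylation (rate ``k_dem_eff``)::

    dM/dt = k_dep * (1 - M) - k_dem_eff * M

A passage of the replication fork divides ``M`` by exactly
``dilution_factor`` (fixed at 2: unsplit H3/H4 tetramers are partitioned onto
two daughter genomes, and newly deposited histones carry no methylation).

Positions below their midlog steady state additionally recover through a fast
remethylation channel (rate ``k_remeth``); co-transcriptional restoration of
H3K4me3 at an active 5' end is much faster than the removal of excess marks,
and without this asymmetry a post-replication undershoot would persist for most
of a cell cycle, which is not what synchronized time courses show.
"""

from __future__ import annotations

from typing import Dict, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

InductionClass = Literal["none", "heat", "alpha", "galactose"]
Protocol = Literal["CCA", "CCTS", "galdex"]

#: which gene class each synchrony protocol induces during its arrest
PROTOCOL_INDUCED_CLASS: Dict[str, str] = {
    "CCA": "alpha",       # alpha-factor arrest induces pheromone-response genes
    "CCTS": "heat",       # 37 C arrest induces heat-shock genes
    "galdex": "galactose",  # galactose growth induces GAL genes
}


class KineticParams(BaseModel):
    """Rates and schedule of the generative model.

    Rates are per minute; the dilution factor is dimensionless and pinned to
    the two-fold ceiling that unsplit tetramers impose.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    k_dep_mid: float = 0.005
    k_dep_induced: float = 0.05
    k_dem: float
    jhd2_scale: float = 0.25
    dilution_factor: float = 2.0
    five_prime_cutoff_bp: float = 500.0
    three_prime_dem_scale: float = 0.2
    cycle_length_min: float = 60.0
    s_phase_window: Tuple[float, float] = (10.0, 35.0)
    noise_sigma_log2: float = 0.15
    seed: int = 0
    # population synchrony dispersion (s.d. of per-cell replication timing, min):
    # the array measures ~1e7 imperfectly synchronized cells, so the measured
    # channel averages trajectories over this jitter; the single-lineage truth
    # trajectory keeps its instantaneous two-fold dilution
    sync_sd_min: float = 4.0
    # fast return-to-baseline channel for under-methylated positions (see module docstring)
    k_remeth: float = 0.15
    # optional lag before demethylation becomes active after release (default: none)
    demethylation_onset_min: float = 0.0
    # derive the effective midlog deposition rate from each locus baseline so that
    # the midlog steady state equals the annotated baseline fraction
    tie_deposition_to_baseline: bool = True

    @field_validator(
        "k_dep_mid", "k_dep_induced", "k_dem", "k_remeth",
        "noise_sigma_log2", "five_prime_cutoff_bp", "demethylation_onset_min",
        "sync_sd_min",
    )
    @classmethod
    def _nonnegative(cls, v: float, info) -> float:
        import math

        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{info.field_name} must be finite and >= 0, got {v}")
        return v

    @field_validator("jhd2_scale")
    @classmethod
    def _jhd2_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"jhd2_scale must be in [0, 1), got {v}")
        return v

    @field_validator("three_prime_dem_scale")
    @classmethod
    def _scale_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"three_prime_dem_scale must be in [0, 1], got {v}")
        return v

    @field_validator("dilution_factor")
    @classmethod
    def _dilution_is_two(cls, v: float) -> float:
        if v != 2.0:
            raise ValueError("dilution_factor is fixed at 2 (unsplit tetramers)")
        return v

    @field_validator("cycle_length_min")
    @classmethod
    def _positive_cycle(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("cycle_length_min must be > 0")
        return v

    @model_validator(mode="after")
    def _s_window_in_cycle(self) -> "KineticParams":
        lo, hi = self.s_phase_window
        if not (0 <= lo < hi <= self.cycle_length_min):
            raise ValueError(
                f"s_phase_window {self.s_phase_window} must lie inside "
                f"[0, {self.cycle_length_min}]"
            )
        return self


class LocusSpec(BaseModel):
    """One nucleosome position with its covariates.

    ``arrest_excess_log2`` is the log2 excess over the midlog baseline that the
    locus reaches during arrest *if* its induction class matches the arrest
    stimulus of the condition being simulated; otherwise the locus starts at
    baseline.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    nucleosome_id: str
    replication_time_min: float
    tss_distance_bp: float
    induction_class: InductionClass = "none"
    arrest_excess_log2: float = 0.0
    baseline_fraction: float = 0.3
    # per-locus multiplier on the demethylation rate (locus-to-locus variability
    # in demethylase targeting; 1 = the global rate)
    k_dem_scale: float = 1.0

    @field_validator("replication_time_min", "tss_distance_bp")
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("baseline_fraction")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError(f"baseline_fraction must be in (0, 1), got {v}")
        return v

    @field_validator("k_dem_scale")
    @classmethod
    def _pos_scale(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"k_dem_scale must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _arrest_fraction_bounded(self) -> "LocusSpec":
        if self.baseline_fraction * 2.0 ** self.arrest_excess_log2 > 1.0 + 1e-12:
            raise ValueError(
                f"{self.nucleosome_id}: baseline_fraction * 2**arrest_excess_log2 "
                "exceeds 1 (methylated fraction cannot exceed 1)"
            )
        return self


class ConditionSpec(BaseModel):
    """One experimental arm: synchrony protocol, replication status, genotype, grid."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    protocol: Protocol
    replication_enabled: bool = True
    # stimulus active on [t_i, t_{i+1}) where the flag is taken at t_i; None
    # means the inducing stimulus is off for the whole (post-release) grid
    stimulus_schedule: Optional[Dict[float, bool]] = None
    kdem_multiplier: float = 1.0
    time_grid_min: Tuple[float, ...]
    induced_class: Optional[InductionClass] = None
    # classes induced during the pre-release arrest (default: the protocol's
    # own class); e.g. alpha-factor + galactose arrest induces both
    arrest_classes: Optional[Tuple[InductionClass, ...]] = None
    # classes whose inducing stimulus persists through the whole grid (e.g.
    # alpha-factor maintained during a galactose->dextrose shift); their
    # arrest-phase steady state is held
    sustained_classes: Tuple[InductionClass, ...] = ()

    @field_validator("kdem_multiplier")
    @classmethod
    def _mult_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"kdem_multiplier must be in [0, 1], got {v}")
        return v

    @field_validator("time_grid_min")
    @classmethod
    def _increasing(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if len(v) < 2:
            raise ValueError("time_grid_min needs at least two points")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("time_grid_min must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _schedule_covers_grid(self) -> "ConditionSpec":
        if self.stimulus_schedule is not None:
            missing = [t for t in self.time_grid_min if t not in self.stimulus_schedule]
            if missing:
                raise ValueError(
                    f"stimulus_schedule missing grid times {missing[:5]}"
                )
        return self

    @property
    def effective_induced_class(self) -> str:
        return self.induced_class or PROTOCOL_INDUCED_CLASS[self.protocol]

    @property
    def effective_arrest_classes(self) -> Tuple[str, ...]:
        if self.arrest_classes is not None:
            return self.arrest_classes
        return (self.effective_induced_class,)

    def stimulus_active(self, t: float) -> bool:
        if self.stimulus_schedule is None:
            return False
        return bool(self.stimulus_schedule[t])
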