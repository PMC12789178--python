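"""Configuration objects for the synthetic-data generator and pipeline.

All knobs of the generator live on :class:`SimulationConfig` so that a
single structured file (YAML) can describe a complete simulated study.
Validation errors always name the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariant."""


# fields that must be strictly positive / non-negative counts etc.
_POSITIVE = {
    "sampling_interval",
    "logger_accuracy",
    "chronotype_sd",
    "onset_mean_hour",
}
_NONNEGATIVE = {
    "v_female",
    "v_female_year",
    "v_nestbox",
    "v_residual",
    "laydate_resid_sd",
    "clutch_resid_sd",
    "date_effect_sd",
    "measurement_stagger",
    "heavy_tail_prob",
    "heavy_tail_scale",
    "noise_sd",
    "hidden_hatchling_prob",
    "brood_failure_prob",
    "desertion_prob",
    "prehatch_failure_prob",
    "female_weight_resid_sd",
    "nestling_brood_sd",
    "nestling_resid_sd",
}
_COUNTS = {"n_females", "n_years", "onsets_per_female"}
_PROBS = {
    "heavy_tail_prob",
    "hidden_hatchling_prob",
    "brood_failure_prob",
    "desertion_prob",
    "prehatch_failure_prob",
    "nestbox_move_prob",
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic breeding population and logger traces.

    Variance components (``v_*``) are in squared standard-deviation
    units of the standardised onset; lay-date effects are in days per
    (squared) chronotype unit; temperatures in degrees Celsius; the
    sampling interval in minutes.
    """

    seed: int = 1

    # population design
    n_females: int = 164
    n_years: int = 3
    onsets_per_female: int = 10

    # onset variance components (z^2 units)
    v_female: float = 0.15
    v_female_year: float = 0.06
    v_nestbox: float = 0.0
    v_residual: float = 0.79

    # latent chronotype and its life-history effects
    chronotype_sd: float = 0.45
    linear_laydate_effect: float = 0.0
    quad_laydate_effect: float = 0.0
    laydate_resid_sd: float = 5.0
    laydate_intercept: float = 25.0
    year_effects: Sequence[float] | None = None

    # clutch model
    clutch_intercept: float = 9.0
    clutch_laydate_slope: float = -0.055
    clutch_resid_sd: float = 1.3

    # hatch / fledge / second-brood links (logit scale)
    hatch_logit_intercept: float = 2.2
    hatch_chrono_linear: float = 0.0
    hidden_hatchling_prob: float = 0.08
    fledge_logit_intercept: float = 1.6
    fledge_chrono_linear: float = 0.0
    brood_failure_prob: float = 0.10
    desertion_prob: float = 0.03
    prehatch_failure_prob: float = 0.012
    second_brood_logit_intercept: float = 0.3
    second_brood_fledgling_slope: float = 0.0
    second_brood_laydate_slope: float = -0.08
    second_brood_chrono_linear: float = 0.0

    # condition / biometrics
    female_weight_intercept: float = 18.0
    female_weight_tarsus_slope: float = 0.5
    female_weight_time_slope: float = 0.05
    female_weight_chrono_linear: float = 0.0
    female_weight_resid_sd: float = 0.8
    tarsus_mean: float = 19.5
    tarsus_sd: float = 0.6
    nestling_weight_intercept: float = 17.5
    nestling_age_slope: float = 0.4
    nestling_brood_sd: float = 0.6
    nestling_resid_sd: float = 0.9
    nestling_chrono_linear: float = 0.0

    # nest-box turnover: probability a female moves to a different box
    # in a later year (full fidelity would confound female and box)
    nestbox_move_prob: float = 0.4

    # study entry: "staggered" recruits females uniformly across years
    # (so first measured years differ, as in a monitored wild population);
    # "all" has every female present in every year (balanced designs for
    # variance-component recovery)
    entry_mode: str = "staggered"

    # onset-table structure
    onset_mean_hour: float = 6.2
    date_effect_sd: float = 0.0
    measurement_stagger: int = 0
    heavy_tail_prob: float = 0.0
    heavy_tail_scale: float = 1.5

    # logger physics
    logger_accuracy: float = 0.0625
    sampling_interval: int = 3
    incubation_temp: float = 35.0
    noise_sd: float = 0.05
    tau_off_min: float = 8.0
    tau_on_min: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in _COUNTS:
                if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                    raise ConfigError(f"{f.name} must be an integer >= 1, got {v!r}")
            elif f.name in _POSITIVE:
                if not _is_number(v) or v <= 0:
                    raise ConfigError(f"{f.name} must be > 0, got {v!r}")
            elif f.name in _NONNEGATIVE:
                if not _is_number(v) or v < 0:
                    raise ConfigError(f"{f.name} must be >= 0, got {v!r}")
            if f.name in _PROBS and not 0 <= v <= 1:
                raise ConfigError(f"{f.name} must lie in [0, 1], got {v!r}")
        if self.year_effects is not None and len(self.year_effects) != self.n_years:
            raise ConfigError(
                f"year_effects must have length n_years={self.n_years}, "
                f"got {len(self.year_effects)}"
            )
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if self.entry_mode not in ("staggered", "all"):
            raise ConfigError(
                f"entry_mode must be 'staggered' or 'all', got {self.entry_mode!r}"
            )

    def resolved_year_effects(self) -> list[float]:
        """Per-year lay-date offsets (days); defaults cycle 0, +3, -2."""
        if self.year_effects is not None:
            return [float(v) for v in self.year_effects]
        base = [0.0, 3.0, -2.0, 1.0, -1.0]
        return [base[i % len(base)] for i in range(self.n_years)]

    def years(self) -> list[int]:
        """Calendar years of the simulated study (used for timestamps)."""
        return [2020 + i for i in range(self.n_years)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["year_effects"] is not None:
            data["year_effects"] = list(data["year_effects"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)
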