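"""Seeded synthetic breeding populations and nest-temperature traces.

The generator emulates the two input kinds of the pipeline with known
ground truth: (a) tabular breeding records driven by a latent female
chronotype ``C`` (Gaussian, configurable SD) whose life-history effects
are configurable and default to zero, and (b) nest-temperature logger
traces with programmed off-bouts, so that detection, standardisation,
repeatability and selection fitting can all be verified by recovery.

Every stream of randomness derives from the single config seed via
named sub-streams, so each table is individually reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronest.bout_detect import TemperatureTrace
from chronest.config import ConfigError, SimulationConfig

__all__ = [
    "SimTruth",
    "AmbientTrace",
    "gen_population",
    "gen_onset_table",
    "gen_ambient_trace",
    "gen_nest_temperature",
    "gen_biometric_tables",
    "truth_chronotypes",
]

# fixed sub-stream tags so each table is reproducible on its own
_STREAMS = {
    "population": 11,
    "onsets": 12,
    "ambient": 13,
    "nest_temp": 14,
    "biometrics": 15,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class AmbientTrace:
    """30-minute binned ambient reference series."""

    times: pd.DatetimeIndex
    temp: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times.asi8) <= 0):
            raise ConfigError("ambient timestamps must be strictly increasing")
        steps = np.unique(np.diff(self.times.asi8))
        if len(steps) > 1:
            raise ConfigError("ambient grid must be regular (30-min spacing)")

    def as_series(self) -> pd.Series:
        return pd.Series(self.temp, index=self.times)


@dataclass
class SimTruth:
    """Ground-truth ledger of a simulated study.

    ``females``: one row per female (latent chronotype).
    ``female_years``: per female-year effects, true lay dates/clutches.
    ``onsets``: programmed daily onsets, filled by :func:`gen_onset_table`.
    """

    females: pd.DataFrame
    female_years: pd.DataFrame
    onsets: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# population


def gen_population(config: SimulationConfig) -> tuple[SimTruth, pd.DataFrame]:
    """Simulate females, latent chronotypes and breeding records.

    True lay date is ``intercept + year effect + linear*C + quad*C^2 +
    Gaussian noise``; clutch size declines with relative lay date;
    hatch, fledge and second-brood outcomes come from binomial/Bernoulli
    links whose chronotype effects default to zero.
    """
    config.validate()
    rng = _rng(config.seed, "population")
    nf, ny = config.n_females, config.n_years
    years = config.years()
    year_eff = config.resolved_year_effects()

    female_ids = [f"F{i:04d}" for i in range(nf)]
    C = rng.normal(0.0, config.chronotype_sd, nf)
    if config.entry_mode == "staggered" and ny > 1:
        entry = rng.integers(0, ny, nf)
    else:
        entry = np.zeros(nf, dtype=int)
    females = pd.DataFrame(
        {"female_id": female_ids, "latent_chronotype": C, "entry_year_index": entry}
    )

    box_pool = [f"B{i:04d}" for i in range(nf)]
    box_eff = rng.normal(0.0, np.sqrt(config.v_nestbox), nf)
    box_of = np.arange(nf)  # box index per female, updated each year

    rows = []
    broods = []
    for yi, year in enumerate(years):
        if yi > 0 and config.nestbox_move_prob > 0:
            movers = rng.random(nf) < config.nestbox_move_prob
            if movers.sum() > 1:
                box_of = box_of.copy()
                box_of[movers] = rng.permutation(box_of[movers])
        fy_dev = rng.normal(0.0, np.sqrt(config.v_female_year), nf)
        lay = (
            config.laydate_intercept
            + year_eff[yi]
            + config.linear_laydate_effect * C
            + config.quad_laydate_effect * C**2
            + rng.normal(0.0, config.laydate_resid_sd, nf)
        )
        lay = np.round(lay).astype(int)
        rel_lay = lay - (config.laydate_intercept + year_eff[yi])
        clutch = np.round(
            config.clutch_intercept
            + config.clutch_laydate_slope * rel_lay
            + rng.normal(0.0, config.clutch_resid_sd, nf)
        ).astype(int)
        clutch = np.clip(clutch, 1, 15)
        inc_start = lay + clutch - 1
        hatch = inc_start + 13

        p_hatch = _sigmoid(
            config.hatch_logit_intercept + config.hatch_chrono_linear * C
        )
        hatchlings = rng.binomial(clutch, p_hatch)
        prehatch_fail = rng.random(nf) < config.prehatch_failure_prob
        hatchlings = np.where(prehatch_fail, 0, hatchlings)
        unhatched = clutch - hatchlings
        hidden = rng.binomial(hatchlings, config.hidden_hatchling_prob)
        max_obs = hatchlings - hidden

        p_fledge = _sigmoid(
            config.fledge_logit_intercept + config.fledge_chrono_linear * C
        )
        fledglings = rng.binomial(max_obs, p_fledge)
        brood_fail = rng.random(nf) < config.brood_failure_prob
        fledglings = np.where(brood_fail, 0, fledglings)
        success = (fledglings >= 1).astype(int)
        deserted = (rng.random(nf) < config.desertion_prob).astype(int)

        sb_logit = (
            config.second_brood_logit_intercept
            + config.second_brood_fledgling_slope * fledglings
            + config.second_brood_laydate_slope * rel_lay
            + config.second_brood_chrono_linear * C
        )
        second = np.where(success == 1, rng.binomial(1, _sigmoid(sb_logit)), 0)

        for i in range(nf):
            if entry[i] > yi:
                continue
            rows.append(
                {
                    "female_id": female_ids[i],
                    "year": year,
                    "fy_deviation": fy_dev[i],
                    "nest_box": box_pool[box_of[i]],
                    "nestbox_effect": box_eff[box_of[i]],
                    "lay_date_true": int(lay[i]),
                    "clutch_true": int(clutch[i]),
                    "hatch_date_true": int(hatch[i]),
                    "hatchlings_true": int(hatchlings[i]),
                }
            )
            broods.append(
                {
                    "brood_id": f"{year}_{female_ids[i]}",
                    "female_id": female_ids[i],
                    "year": year,
                    "nest_box": box_pool[box_of[i]],
                    "lay_date": int(lay[i]),
                    "clutch_size": int(clutch[i]),
                    "incubation_start": int(inc_start[i]),
                    "hatch_date": int(hatch[i]),
                    "max_observed_nestlings": int(max_obs[i]),
                    "unhatched_eggs": int(unhatched[i]),
                    "n_fledglings": int(fledglings[i]),
                    "fledge_success": int(success[i]),
                    "second_brood": int(second[i]),
                    "deserted_flag": int(deserted[i]),
                    "failed_prehatch_flag": int(prehatch_fail[i]),
                }
            )
    truth = SimTruth(females=females, female_years=pd.DataFrame(rows))
    return truth, pd.DataFrame(broods)


# ---------------------------------------------------------------------------
# onset table


def gen_onset_table(config: SimulationConfig, truth: SimTruth) -> pd.DataFrame:
    """Programmed daily activity onsets for every female-year.

    Onset(hours) = date mean + female effect + female-year effect +
    nest-box effect + residual, with the female effect proportional to
    the latent chronotype scaled to variance ``v_female``.  All females
    of a year share a common measurement window (optionally staggered),
    so every retained date has at least three females whenever the
    population does.
    """
    config.validate()
    rng = _rng(config.seed, "onsets")
    years = config.years()
    year_eff = config.resolved_year_effects()

    C = truth.females.set_index("female_id")["latent_chronotype"]
    female_effect = C * (np.sqrt(config.v_female) / config.chronotype_sd)

    fy = truth.female_years.set_index(["female_id", "year"])
    rows = []
    for yi, year in enumerate(years):
        base = int(round(config.laydate_intercept + year_eff[yi] + config.clutch_intercept + 2))
        date_eff = {
            d: rng.normal(0.0, config.date_effect_sd) if config.date_effect_sd > 0 else 0.0
            for d in range(base, base + config.onsets_per_female + config.measurement_stagger + 1)
        }
        present = truth.female_years.loc[
            truth.female_years["year"] == year, "female_id"
        ]
        for fid in present:
            rec = fy.loc[(fid, year)]
            stagger = (
                int(rng.integers(0, config.measurement_stagger + 1))
                if config.measurement_stagger > 0
                else 0
            )
            for j in range(config.onsets_per_female):
                date = base + stagger + j
                onset = (
                    config.onset_mean_hour
                    + date_eff[date]
                    + female_effect[fid]
                    + rec["fy_deviation"]
                    + rec["nestbox_effect"]
                    + rng.normal(0.0, np.sqrt(config.v_residual))
                )
                if config.heavy_tail_prob > 0 and rng.random() < config.heavy_tail_prob:
                    onset -= rng.exponential(config.heavy_tail_scale)
                onset = float(np.clip(onset, 0.0, 23.99))
                rows.append(
                    {
                        "female_id": fid,
                        "brood_id": f"{year}_{fid}",
                        "nest_box": rec["nest_box"],
                        "year": year,
                        "date": date,
                        "onset": onset,
                        "breeding_day": date - int(rec["hatch_date_true"]),
                        "stage": "incubation"
                        if date - int(rec["hatch_date_true"]) < 0
                        else "provisioning",
                    }
                )
    onsets = pd.DataFrame(rows)
    truth.onsets = onsets.copy()
    return onsets


def truth_chronotypes(truth: SimTruth, broods: pd.DataFrame) -> pd.DataFrame:
    """Chronotype table built from the latent truth, not from onsets.

    One row per female with her *latent* chronotype attached to the
    first brood of her first (entry) year.  Recovery experiments use
    this to isolate the selection-model machinery from the attenuation
    that noisy measured chronotypes introduce.
    """
    fem = truth.females
    first_year = fem["entry_year_index"].to_numpy() + int(broods["year"].min())
    tab = pd.DataFrame(
        {
            "female_id": fem["female_id"],
            "chronotype": fem["latent_chronotype"],
            "year": first_year,
        }
    )
    tab["brood_id"] = tab["year"].astype(str) + "_" + tab["female_id"]
    tab["n_onsets"] = 0
    return tab[["female_id", "chronotype", "n_onsets", "year", "brood_id"]]


# ---------------------------------------------------------------------------
# traces


def gen_ambient_trace(
    days: int,
    seed: int,
    start: dt.date | None = None,
    base: float = 10.0,
    amplitude: float = 6.0,
    noise_sd: float = 0.5,
) -> AmbientTrace:
    """Smooth diel ambient sinusoid at 30-min resolution, 48 points/day.

    Temperature peaks mid-afternoon (15:00) and troughs before dawn.
    """
    if days < 1:
        raise ConfigError(f"days must be >= 1, got {days}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAMS["ambient"]]))
    if start is None:
        start = dt.date(2021, 4, 1)
    times = pd.date_range(pd.Timestamp(start), periods=days * 48, freq="30min")
    hours = times.hour + times.minute / 60.0
    temp = base + amplitude * np.cos(2 * np.pi * (hours - 15.0) / 24.0)
    temp = temp + rng.normal(0.0, noise_sd, len(times))
    return AmbientTrace(times=times, temp=temp)


def gen_nest_temperature(
    schedule: dict[dt.date, list[tuple[float, float]]],
    ambient: AmbientTrace,
    config: SimulationConfig,
    nest_id: str = "N0000",
    incubation_start: dt.date | None = None,
) -> TemperatureTrace:
    """Nest-temperature trace realising a programmed off-bout schedule.

    ``schedule`` maps dates to ``(start_hour, duration_min)`` off-bouts.
    During on-bouts the nest relaxes toward the incubation plateau with
    time constant ``tau_on_min``; during off-bouts it relaxes toward
    ambient with ``tau_off_min``.  Nights outside programmed off-bouts
    are continuous on-bouts.  Before ``incubation_start`` (first date
    with nocturnal incubation) the nest follows ambient.  Gaussian
    observation noise is added and values are quantised to the logger
    accuracy.
    """
    config.validate()
    rng = _rng(config.seed, "nest_temp")
    t0, t1 = ambient.times[0], ambient.times[-1]
    step = pd.Timedelta(minutes=config.sampling_interval)
    times = pd.date_range(t0, t1, freq=step)
    amb = np.interp(
        times.asi8.astype(float),
        ambient.times.asi8.astype(float),
        ambient.temp,
    )

    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for date, bouts in schedule.items():
        for start_hour, dur_min in bouts:
            s = pd.Timestamp(date) + pd.Timedelta(hours=float(start_hour))
            e = s + pd.Timedelta(minutes=float(dur_min))
            if s < t0 or e > t1 + step:
                raise ConfigError(
                    f"off-bout {s} .. {e} outside trace span {t0} .. {t1}"
                )
            intervals.append((s, e))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ConfigError(f"overlapping off-bouts at {s2}")

    absent = np.zeros(len(times), dtype=bool)
    for s, e in intervals:
        absent |= (times >= s) & (times < e)
    if incubation_start is not None:
        sitting_from = pd.Timestamp(incubation_start) - pd.Timedelta(hours=3)
        absent |= np.asarray(times < sitting_from)

    dt_min = config.sampling_interval
    k_off = 1.0 - np.exp(-dt_min / config.tau_off_min)
    k_on = 1.0 - np.exp(-dt_min / config.tau_on_min)
    temp = np.empty(len(times))
    temp[0] = amb[0] if absent[0] else config.incubation_temp
    for i in range(1, len(times)):
        if absent[i]:
            temp[i] = temp[i - 1] + (amb[i] - temp[i - 1]) * k_off
        else:
            temp[i] = temp[i - 1] + (config.incubation_temp - temp[i - 1]) * k_on
    temp = temp + rng.normal(0.0, config.noise_sd, len(times))
    acc = config.logger_accuracy
    temp = np.round(temp / acc) * acc
    return TemperatureTrace(nest_id, times, temp, acc, amb)


# ---------------------------------------------------------------------------
# biometrics


def gen_biometric_tables(
    config: SimulationConfig, truth: SimTruth, broods: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Female-condition and nestling-biometric tables.

    Returns ``(condition, nestlings)``.  Condition: one row per female
    and year (weight, tarsus, time of day).  Nestlings: one row per
    fledged nestling with age 14-16 days, weight, tarsus and P3 feather
    length, sharing a brood-level random effect.
    """
    config.validate()
    rng = _rng(config.seed, "biometrics")
    C = truth.females.set_index("female_id")["latent_chronotype"]

    cond_rows = []
    nest_rows = []
    for _, b in broods.iterrows():
        c = C[b["female_id"]]
        tarsus = rng.normal(config.tarsus_mean, config.tarsus_sd)
        tod = rng.uniform(7.0, 19.0)
        weight = (
            config.female_weight_intercept
            + config.female_weight_tarsus_slope * (tarsus - config.tarsus_mean)
            + config.female_weight_time_slope * (tod - 13.0)
            + config.female_weight_chrono_linear * c
            + rng.normal(0.0, config.female_weight_resid_sd)
        )
        cond_rows.append(
            {
                "female_id": b["female_id"],
                "year": b["year"],
                "weight": weight,
                "tarsus": tarsus,
                "time_of_day": tod,
            }
        )
        brood_eff = rng.normal(0.0, config.nestling_brood_sd)
        for _ in range(int(b["n_fledglings"])):
            age = int(rng.integers(14, 17))
            base_w = (
                config.nestling_weight_intercept
                + config.nestling_age_slope * (age - 15)
                + config.nestling_chrono_linear * c
                + brood_eff
            )
            nest_rows.append(
                {
                    "brood_id": b["brood_id"],
                    "female_id": b["female_id"],
                    "year": b["year"],
                    "chick_age": age,
                    "weight": base_w + rng.normal(0.0, config.nestling_resid_sd),
                    "tarsus": 19.5
                    + 0.2 * (age - 15)
                    + 0.5 * brood_eff
                    + rng.normal(0.0, 0.5),
                    "p3": 45.0
                    + 1.5 * (age - 15)
                    + 1.0 * brood_eff
                    + rng.normal(0.0, 2.0),
                    "time_of_day": rng.uniform(10.0, 18.0),
                }
            )
    condition = pd.DataFrame(cond_rows)
    nestlings = pd.DataFrame(
        nest_rows,
        columns=[
            "brood_id",
            "female_id",
            "year",
            "chick_age",
            "weight",
            "tarsus",
            "p3",
            "time_of_day",
        ],
    )
    return condition, nestlings
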