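"""Conspecific standardisation of activity onsets and chronotype.

Raw onsets shift day to day with day length and weather, so a female's
onset is expressed relative to all females measured on the same date:

    z = (onset - date mean) / date SD

The date SD is the sample (n-1) standard deviation; dates with fewer
than three females (or zero spread) are dropped, broods with fewer than
two retained onsets are dropped, and a female's chronotype is the mean
z of her first measured brood in her first measured year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "standardise_onsets",
    "filter_measurement_set",
    "compute_chronotype",
    "estimate_lay_date",
    "centre_covariates",
]


class StandardiseError(ValueError):
    pass


def standardise_onsets(
    onsets: pd.DataFrame,
    min_females: int = 3,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-standardise onsets within (year, date) across females.

    Expects one onset per female per date.  Returns ``(std, log)``
    where ``std`` adds columns ``z``, ``date_n``, ``date_mean`` and
    ``date_sd`` and ``log`` records dropped dates with reasons.
    """
    required = {"female_id", "year", "date", "onset"}
    missing = required - set(onsets.columns)
    if missing:
        raise StandardiseError(f"onset table missing columns {sorted(missing)}")
    dup = onsets.duplicated(subset=["female_id", "year", "date"])
    if dup.any():
        pairs = onsets.loc[dup, ["female_id", "year", "date"]].head(5)
        raise StandardiseError(
            f"duplicate (female, date) onsets, e.g. {pairs.to_dict('records')}"
        )

    df = onsets.copy()
    grp = df.groupby(["year", "date"])["onset"]
    df["date_n"] = grp.transform("count")
    df["date_mean"] = grp.transform("mean")
    df["date_sd"] = grp.transform(lambda s: s.std(ddof=ddof))

    log_rows = []
    few = df["date_n"] < min_females
    flat = (df["date_sd"] <= 0) | df["date_sd"].isna()
    for (year, date), sub in df[few].groupby(["year", "date"]):
        log_rows.append(
            {"year": year, "date": date, "n": len(sub), "reason": "fewer females than minimum"}
        )
    for (year, date), sub in df[~few & flat].groupby(["year", "date"]):
        log_rows.append({"year": year, "date": date, "n": len(sub), "reason": "zero spread"})

    keep = df[~few & ~flat].copy()
    keep["z"] = (keep["onset"] - keep["date_mean"]) / keep["date_sd"]
    log = pd.DataFrame(log_rows, columns=["year", "date", "n", "reason"])
    return keep.reset_index(drop=True), log


def filter_measurement_set(
    std_onsets: pd.DataFrame, min_onsets: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep broods with at least ``min_onsets`` standardised onsets."""
    counts = std_onsets.groupby("brood_id")["z"].transform("count")
    dropped = std_onsets[counts < min_onsets]
    log = (
        dropped.groupby("brood_id")
        .size()
        .rename("n_onsets")
        .reset_index()
        .assign(reason="fewer onsets than minimum")
    )
    return std_onsets[counts >= min_onsets].reset_index(drop=True), log


def compute_chronotype(
    std_onsets: pd.DataFrame,
    broods: pd.DataFrame | None = None,
    exclude_females: "set[str] | None" = None,
) -> pd.DataFrame:
    """Per-female chronotype: mean z of the first brood, first year.

    When a female has broods in several years only her earliest
    measured year contributes; within that year the first brood is the
    one with the earliest lay date (ties: earliest incubation start,
    then lowest brood id), resolved from ``broods`` when given,
    otherwise by lowest brood id.
    """
    df = std_onsets
    if exclude_females:
        df = df[~df["female_id"].isin(exclude_females)]
    if df.empty:
        return pd.DataFrame(
            columns=["female_id", "chronotype", "n_onsets", "year", "brood_id"]
        )

    order = None
    if broods is not None:
        cols = ["brood_id", "lay_date"]
        if "incubation_start" in broods.columns:
            cols.append("incubation_start")
        order = broods[cols].set_index("brood_id")

    rows = []
    for fid, sub in df.groupby("female_id"):
        first_year = sub["year"].min()
        year_sub = sub[sub["year"] == first_year]
        brood_ids = sorted(year_sub["brood_id"].unique())
        if order is not None and len(brood_ids) > 1:

            def sort_key(bid):
                if bid in order.index:
                    rec = order.loc[bid]
                    return (
                        rec.get("lay_date", np.inf),
                        rec.get("incubation_start", np.inf),
                        bid,
                    )
                return (np.inf, np.inf, bid)

            brood_ids = sorted(brood_ids, key=sort_key)
        first_brood = brood_ids[0]
        zs = year_sub.loc[year_sub["brood_id"] == first_brood, "z"]
        rows.append(
            {
                "female_id": fid,
                "chronotype": float(zs.mean()),
                "n_onsets": int(len(zs)),
                "year": first_year,
                "brood_id": first_brood,
            }
        )
    return pd.DataFrame(rows)


def estimate_lay_date(incubation_start, clutch_size):
    """Back-calculate first-egg date: incubation start - clutch + 1.

    Assumes one egg laid per day and incubation starting on the day of
    clutch completion.  Accepts scalars or arrays.
    """
    clutch = np.asarray(clutch_size)
    if np.any(clutch < 1):
        raise StandardiseError("clutch_size must be >= 1")
    out = np.asarray(incubation_start) - clutch + 1
    if out.ndim == 0:
        return out.item()
    return out


def centre_covariates(
    broods: pd.DataFrame, columns: "tuple[str, ...]" = ("lay_date", "hatch_date")
) -> pd.DataFrame:
    """Within-year mean-centre timing covariates (adds ``*_c`` columns)."""
    out = broods.copy()
    for col in columns:
        if col not in out.columns:
            continue
        out[f"{col}_c"] = out[col] - out.groupby("year")[col].transform("mean")
    return out
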