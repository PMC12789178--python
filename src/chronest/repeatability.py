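"""Repeatability of standardised onsets from variance components.

The standardised onset is modelled with fixed effects Year, April day,
their interaction, and centred breeding day plus its square (onsets
drift later toward hatching and earlier again afterwards), and random
intercepts for Female, Female-Year and Nest-box.  Repeatabilities are
intraclass correlations:

    r_across  = V(Female) / V(total)
    r_within  = (V(Female) + V(Female_Year)) / V(total)

with V(total) the sum of all four components.  Because the reported
totals could in principle exclude the (often zero) nest-box component,
both denominators are computed.  Random-effect tests are single-df
likelihood-ratio tests on REML fits; fixed-effect tests refit by ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronest.lmm import CrossedLMMFit, LMMError, fit_crossed_lmm, lrt

__all__ = [
    "VarianceComponents",
    "RepeatabilityResult",
    "fit_onset_lmm",
    "compute_repeatabilities",
    "lrt_random_effect",
    "fixed_effect_lrt",
    "repeatability_report",
]

RANDOM_FACTORS = ("female", "female_year", "nest_box")


@dataclass
class VarianceComponents:
    v_female: float
    v_female_year: float
    v_nestbox: float
    v_residual: float
    loglik: float
    n_obs: int
    n_females: int
    n_female_years: int
    n_nestboxes: int
    fit: CrossedLMMFit | None = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return self.v_female + self.v_female_year + self.v_nestbox + self.v_residual

    @property
    def total_excl_nestbox(self) -> float:
        return self.v_female + self.v_female_year + self.v_residual


@dataclass
class RepeatabilityResult:
    r_within_year: float
    r_across_year: float
    r_within_excl_nestbox: float
    r_across_excl_nestbox: float
    components: VarianceComponents
    lrt_tests: dict[str, tuple[float, int, float]] = field(default_factory=dict)


def _design(std_onsets: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: Year, April day, Year x April day, breeding
    day (centred) and its square.  Continuous covariates are centred for
    conditioning; this changes only the intercept."""
    df = std_onsets
    years = np.sort(df["year"].unique())
    aday = df["date"].to_numpy(dtype=float)
    aday_c = aday - aday.mean()
    bday = df["breeding_day"].to_numpy(dtype=float)
    bday_c = bday - bday.mean()

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for y in years[1:]:
        cols.append((df["year"] == y).to_numpy(dtype=float))
        names.append(f"year[{y}]")
    cols.append(aday_c)
    names.append("april_day")
    for y in years[1:]:
        cols.append((df["year"] == y).to_numpy(dtype=float) * aday_c)
        names.append(f"year[{y}]:april_day")
    cols.append(bday_c)
    names.append("breeding_day")
    cols.append(bday_c**2)
    names.append("breeding_day2")
    X = np.column_stack(cols)
    # drop constant/collinear columns (e.g. a single-year table)
    keep = []
    seen = np.empty((len(df), 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([seen, X[:, j]])
        if np.linalg.matrix_rank(cand) > seen.shape[1]:
            keep.append(j)
            seen = cand
    return X[:, keep], [names[j] for j in keep]


def _groups(std_onsets: pd.DataFrame, factors=RANDOM_FACTORS) -> dict[str, np.ndarray]:
    df = std_onsets
    fy = df["female_id"].astype(str) + "_" + df["year"].astype(str)
    all_groups = {
        "female": df["female_id"].to_numpy(),
        "female_year": fy.to_numpy(),
        "nest_box": df["nest_box"].to_numpy(),
    }
    return {k: all_groups[k] for k in factors}


def fit_onset_lmm(
    std_onsets: pd.DataFrame,
    reml: bool = True,
    factors=RANDOM_FACTORS,
) -> VarianceComponents:
    """REML fit of the standardised-onset mixed model.

    Requires repeated measurements (>= 2 onsets for >= 2 females).
    Singular components come back as exact zeros (e.g. a nest-box
    variance indistinguishable from zero).
    """
    counts = std_onsets.groupby("female_id").size()
    if (counts >= 2).sum() < 2:
        raise LMMError("need >= 2 onsets for >= 2 females")
    y = std_onsets["z"].to_numpy(dtype=float)
    X, names = _design(std_onsets)
    groups = _groups(std_onsets, factors)
    fit = fit_crossed_lmm(y, X, groups, reml=reml, fixed_names=names)
    vc = fit.varcomps
    return VarianceComponents(
        v_female=vc.get("female", 0.0),
        v_female_year=vc.get("female_year", 0.0),
        v_nestbox=vc.get("nest_box", 0.0),
        v_residual=fit.sigma2,
        loglik=fit.loglik,
        n_obs=fit.n_obs,
        n_females=fit.n_levels.get("female", 0),
        n_female_years=fit.n_levels.get("female_year", 0),
        n_nestboxes=fit.n_levels.get("nest_box", 0),
        fit=fit,
    )


def compute_repeatabilities(
    vc: VarianceComponents,
    std_onsets: pd.DataFrame | None = None,
    with_tests: bool = False,
) -> RepeatabilityResult:
    """Within- and across-year repeatability from variance components.

    Optionally adds single-df REML likelihood-ratio tests for each
    random factor (requires the standardised-onset table to refit the
    reduced models).
    """
    if vc.total <= 0:
        raise LMMError("total variance is zero; repeatability undefined")
    res = RepeatabilityResult(
        r_within_year=(vc.v_female + vc.v_female_year) / vc.total,
        r_across_year=vc.v_female / vc.total,
        r_within_excl_nestbox=(vc.v_female + vc.v_female_year) / vc.total_excl_nestbox,
        r_across_excl_nestbox=vc.v_female / vc.total_excl_nestbox,
        components=vc,
    )
    if with_tests:
        if std_onsets is None:
            raise LMMError("std_onsets required for likelihood-ratio tests")
        for factor in RANDOM_FACTORS:
            reduced_factors = tuple(f for f in RANDOM_FACTORS if f != factor)
            reduced = fit_onset_lmm(std_onsets, reml=True, factors=reduced_factors)
            res.lrt_tests[factor] = lrt_random_effect(vc, reduced)
    return res


def lrt_random_effect(
    full: VarianceComponents | CrossedLMMFit,
    reduced: VarianceComponents | CrossedLMMFit,
) -> tuple[float, int, float]:
    """Chi-square(1) LRT for one variance component.

    The statistic is 2(logLik_full - logLik_reduced) on REML fits,
    referred to a 1-df chi-square (no boundary mixture; conservative).
    """
    full_fit = full.fit if isinstance(full, VarianceComponents) else full
    red_fit = reduced.fit if isinstance(reduced, VarianceComponents) else reduced
    if full_fit is not None and red_fit is not None:
        f_names = set(full_fit.n_levels)
        r_names = set(red_fit.n_levels)
        if not (r_names <= f_names and len(f_names - r_names) <= 1):
            raise LMMError(
                "reduced model must drop exactly one random factor of the full model"
            )
        if full_fit.reml != red_fit.reml:
            raise LMMError("full and reduced fits must use the same criterion")
    ll_full = full.loglik
    ll_red = reduced.loglik
    return lrt(ll_full, ll_red, df=1)


def fixed_effect_lrt(
    std_onsets: pd.DataFrame,
    drop: str,
    factors=RANDOM_FACTORS,
) -> tuple[float, int, float]:
    """ML likelihood-ratio test for one fixed-effect term.

    ``drop`` is one of ``"april_day"``, ``"year"``, ``"year:april_day"``,
    ``"breeding_day"``, ``"breeding_day2"``.  Both models are refitted
    by maximum likelihood (REML likelihoods are not comparable across
    fixed structures).
    """
    y = std_onsets["z"].to_numpy(dtype=float)
    X, names = _design(std_onsets)
    groups = _groups(std_onsets, factors)

    if drop == "year":
        gone = [n for n in names if n.startswith("year[") and ":" not in n]
    elif drop == "year:april_day":
        gone = [n for n in names if n.startswith("year[") and n.endswith(":april_day")]
    else:
        gone = [n for n in names if n == drop]
    if not gone:
        raise LMMError(f"term {drop!r} not in the fixed design")
    keep = [i for i, n in enumerate(names) if n not in gone]

    full = fit_crossed_lmm(y, X, groups, reml=False, fixed_names=names)
    reduced = fit_crossed_lmm(
        y, X[:, keep], groups, reml=False, fixed_names=[names[i] for i in keep]
    )
    return lrt(full.loglik, reduced.loglik, df=len(gone))


def repeatability_report(res: RepeatabilityResult) -> pd.DataFrame:
    """Machine-readable one-row-per-quantity report table."""
    vc = res.components
    rows = [
        ("v_female", vc.v_female),
        ("v_female_year", vc.v_female_year),
        ("v_nestbox", vc.v_nestbox),
        ("v_residual", vc.v_residual),
        ("r_within_year", res.r_within_year),
        ("r_across_year", res.r_across_year),
        ("r_within_excl_nestbox", res.r_within_excl_nestbox),
        ("r_across_excl_nestbox", res.r_across_excl_nestbox),
        ("n_obs", vc.n_obs),
        ("n_females", vc.n_females),
        ("n_female_years", vc.n_female_years),
        ("n_nestboxes", vc.n_nestboxes),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    for factor, (stat, dfree, p) in res.lrt_tests.items():
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [
                        (f"lrt_{factor}_stat", stat),
                        (f"lrt_{factor}_df", dfree),
                        (f"lrt_{factor}_p", p),
                    ],
                    columns=["quantity", "value"],
                ),
            ],
            ignore_index=True,
        )
    return df
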