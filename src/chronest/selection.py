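"""Fitness and life-history selection models with backward reduction.

Each response is modelled on the shared base formula

    response = C + C^2 + Year + C:Year + C^2:Year + lay date (centred)

where ``C`` is the female's chronotype, plus response-specific
covariates (time of day, tarsus, chick age, fledgling count ...).
Model families are Gaussian GLM, binomial GLM, or Gaussian mixed with a
brood random intercept (nestling biometrics, to avoid pseudo-
replication of siblings).

Backward elimination respects marginality: a term is droppable only
while no retained higher-order term contains it (interactions before
main effects, quadratic before linear).  At each step the droppable
term with the largest p from its single-term deletion test (F for
Gaussian, deviance chi-square for binomial, ML likelihood ratio for
mixed) is removed if p >= alpha.  Estimates and standard errors are
captured from the model in which the term was last present, i.e.
before dropping it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Term",
    "TermTest",
    "ModelSpec",
    "ModelFit",
    "estimate_hatchlings",
    "build_model_suite",
    "fit_model",
    "stepwise_reduce",
    "simulate_prediction_band",
]


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# terms


@dataclass(frozen=True)
class Term:
    """A model term as a mapping of variables to powers.

    ``Term({"chronotype": 2, "year": 1})`` is the quadratic-chronotype
    by year interaction.  The empty term is the intercept.  ``year`` is
    the only categorical variable; all others enter as numeric powers.
    """

    powers: tuple[tuple[str, int], ...]

    def __init__(self, powers: "dict[str, int] | tuple" = ()):  # noqa: D107
        if isinstance(powers, dict):
            powers = tuple(sorted((k, int(v)) for k, v in powers.items() if v > 0))
        object.__setattr__(self, "powers", tuple(powers))

    @property
    def name(self) -> str:
        if not self.powers:
            return "intercept"
        parts = []
        for var, p in self.powers:
            parts.append(var if p == 1 else f"{var}^{p}")
        return ":".join(parts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.powers)

    def contains(self, other: "Term") -> bool:
        """Marginality: every variable power of ``other`` is matched."""
        if self == other:
            return False
        mine, theirs = self.as_dict(), other.as_dict()
        return all(mine.get(v, 0) >= p for v, p in theirs.items())

    def __repr__(self) -> str:
        return f"Term({self.name})"


def _term_columns(
    term: Term, data: pd.DataFrame, year_levels: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    numeric = np.ones(n)
    for var, p in term.powers:
        if var == "year":
            continue
        if var not in data.columns:
            raise SelectionError(f"column {var!r} missing for term {term.name}")
        numeric = numeric * data[var].to_numpy(dtype=float) ** p
    if term.as_dict().get("year", 0) == 0:
        return numeric[:, None], [term.name]
    cols, names = [], []
    for level in year_levels[1:]:
        dummy = (data["year"] == level).to_numpy(dtype=float)
        cols.append(numeric * dummy)
        names.append(f"{term.name}[{level}]")
    if not cols:  # single-year data: year terms are empty
        return np.empty((n, 0)), []
    return np.column_stack(cols), names


def build_design(
    terms: "list[Term]", data: pd.DataFrame, year_levels: "np.ndarray | None" = None
) -> tuple[np.ndarray, list[str], dict[Term, list[int]]]:
    if year_levels is None:
        year_levels = (
            np.sort(data["year"].unique()) if "year" in data.columns else np.array([])
        )
    blocks, names, slices = [], [], {}
    j = 0
    for t in terms:
        X, nm = _term_columns(t, data, year_levels)
        blocks.append(X)
        names.extend(nm)
        slices[t] = list(range(j, j + X.shape[1]))
        j += X.shape[1]
    return np.column_stack([b for b in blocks if b.shape[1]]), names, slices


# ---------------------------------------------------------------------------
# hatchling estimator


def estimate_hatchlings(clutch_size, max_observed_nestlings, unhatched_eggs, brood_id=None):
    """Hatchling count with half-count uncertainty for unseen nestlings.

    ``m + (c - m - u) / 2``: eggs that were neither counted as
    nestlings nor recovered as unhatched eggs are counted half each.
    The estimate is bounded by ``m <= estimate <= c - u``.
    """
    c = np.asarray(clutch_size, dtype=float)
    m = np.asarray(max_observed_nestlings, dtype=float)
    u = np.asarray(unhatched_eggs, dtype=float)
    bad = c < m + u
    if np.any(bad):
        if brood_id is not None:
            ids = np.asarray(brood_id)[np.atleast_1d(bad)]
            raise SelectionError(
                f"inconsistent counts (clutch < observed + unhatched) for broods "
                f"{ids.tolist()[:5]}"
            )
        raise SelectionError("inconsistent counts: clutch < observed + unhatched")
    out = m + (c - m - u) / 2.0
    if out.ndim == 0:
        return out.item()
    return out


# ---------------------------------------------------------------------------
# model specs


@dataclass
class ModelSpec:
    name: str
    response: str
    family: str  # "gaussian" | "binomial" | "gaussian-mixed"
    terms: list[Term]
    data: pd.DataFrame
    groups: str | None = None  # grouping column for mixed models
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)


def _base_terms(multi_year: bool, with_laydate: bool = True) -> list[Term]:
    C = Term({"chronotype": 1})
    C2 = Term({"chronotype": 2})
    terms = [Term(), C, C2]
    if multi_year:
        terms += [
            Term({"year": 1}),
            Term({"chronotype": 1, "year": 1}),
            Term({"chronotype": 2, "year": 1}),
        ]
    if with_laydate:
        terms.append(Term({"lay_date_c": 1}))
    return terms


def build_model_suite(
    chronotypes: pd.DataFrame,
    broods: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    nestlings: pd.DataFrame | None = None,
    nestling_responses: tuple[str, ...] = ("weight",),
) -> list[ModelSpec]:
    """Assemble the eight-model suite from the joined tables.

    Exclusions follow the study design: females that deserted during
    logger exchange leave the hatchling/fledgling models; pre-hatch
    failures additionally leave the fledge-success model; only
    successful first broods (>= 1 fledgling) enter the second-brood
    model.  Each female appears once, via her first-year chronotype
    brood.  ``nestling_responses`` can expand the nestling spec to
    tarsus and P3 as well.
    """
    need = {"brood_id", "female_id", "year", "lay_date", "clutch_size"}
    missing = need - set(broods.columns)
    if missing:
        raise SelectionError(f"brood table missing columns {sorted(missing)}")

    df = broods.merge(
        chronotypes[["female_id", "brood_id", "chronotype"]],
        on=["female_id", "brood_id"],
        how="inner",
    )
    df = df.copy()
    df["lay_date_c"] = df["lay_date"] - df.groupby("year")["lay_date"].transform("mean")
    if "hatch_date" in df.columns:
        df["hatch_date_c"] = df["hatch_date"] - df.groupby("year")["hatch_date"].transform("mean")
    multi_year = df["year"].nunique() > 1

    def spec(name, response, family, data, extra=(), with_laydate=True, groups=None, meta=None):
        terms = _base_terms(multi_year, with_laydate) + list(extra)
        return ModelSpec(name, response, family, terms, data.reset_index(drop=True), groups, meta or {})

    specs = []
    specs.append(spec("lay_date", "lay_date", "gaussian", df, with_laydate=False))
    specs.append(spec("clutch_size", "clutch_size", "gaussian", df))

    kept = df[df["deserted_flag"] == 0] if "deserted_flag" in df.columns else df
    hd = kept.copy()
    hd["hatchlings"] = estimate_hatchlings(
        hd["clutch_size"], hd["max_observed_nestlings"], hd["unhatched_eggs"],
        brood_id=hd["brood_id"],
    )
    specs.append(spec("hatchlings", "hatchlings", "gaussian", hd,
                      meta={"excluded": "deserters"}))
    specs.append(spec("fledglings", "n_fledglings", "gaussian", kept,
                      meta={"excluded": "deserters"}))

    fs = kept
    if "failed_prehatch_flag" in fs.columns:
        fs = fs[fs["failed_prehatch_flag"] == 0]
    specs.append(spec("fledge_success", "fledge_success", "binomial", fs,
                      meta={"excluded": "deserters + pre-hatch failures"}))

    sb = kept[kept["fledge_success"] == 1]
    specs.append(spec("second_brood", "second_brood", "binomial", sb,
                      extra=[Term({"n_fledglings": 1})],
                      meta={"included": "successful first broods only"}))

    if condition is not None:
        cond = df.merge(
            condition, on=["female_id", "year"], how="inner", suffixes=("", "_cond")
        )
        specs.append(spec(
            "female_weight", "weight", "gaussian", cond,
            extra=[Term({"time_of_day": 1}), Term({"time_of_day": 2}), Term({"tarsus": 1})],
        ))

    if nestlings is not None:
        nst = nestlings.merge(
            df[["brood_id", "chronotype", "lay_date_c"]
               + (["hatch_date_c"] if "hatch_date_c" in df.columns else [])],
            on="brood_id", how="inner",
        ).merge(broods[["brood_id", "n_fledglings"]], on="brood_id", how="left")
        seasonal = Term({"hatch_date_c": 1}) if "hatch_date_c" in nst.columns else Term({"lay_date_c": 1})
        for resp in nestling_responses:
            extra = [seasonal, Term({"chick_age": 1}), Term({"n_fledglings": 1})]
            if resp == "weight":
                extra += [Term({"time_of_day": 1}), Term({"time_of_day": 2})]
            specs.append(ModelSpec(
                f"nestling_{resp}", resp, "gaussian-mixed",
                _base_terms(multi_year, with_laydate=False) + extra,
                nst.reset_index(drop=True), groups="brood_id",
                meta={"random": "brood intercept"},
            ))
    return specs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class TermTest:
    term: Term
    kind: str  # "F" | "Chisq" | "Deviance"
    stat: float
    df: int
    p: float
    estimates: list[tuple[str, float, float]]  # (column, estimate, SE) pre-drop
    dropped: bool
    protected: bool = False


@dataclass
class ModelFit:
    spec: ModelSpec
    terms: list[Term]
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    deviance: float  # residual deviance (binomial) or RSS (gaussian)
    df_resid: float
    n: int
    reduction_path: list[TermTest] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def term_estimates(self, term: Term) -> list[tuple[str, float, float]]:
        out = []
        for name in self.params.index:
            base = name.split("[")[0]
            if base == term.name:
                out.append((name, float(self.params[name]), float(self.bse[name])))
        return out


def fit_model(spec: ModelSpec, terms: "list[Term] | None" = None) -> ModelFit:
    """Maximum-likelihood fit of one model spec.

    Binomial fits that separate perfectly are returned flagged rather
    than raised; mixed fits use ML so that nested fixed-effect
    comparisons are valid.
    """
    if terms is None:
        terms = list(spec.terms)
    data = spec.data
    y = data[spec.response].to_numpy(dtype=float)
    X, names, _ = build_design(terms, data)
    flags = []

    if spec.family == "gaussian":
        res = sm.OLS(y, X).fit()
        dev = float(res.ssr)
        llf, df_resid = float(res.llf), float(res.df_resid)
        params, bse = res.params, res.bse
        cov = res.cov_params()
    elif spec.family == "binomial":
        if len(np.unique(y)) < 2:
            flags.append("degenerate response (single class)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            except Exception as exc:  # perfect separation and friends
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=25, tol=1e-4
                )
                flags.append(f"irls trouble: {type(exc).__name__}")
            dev = float(res.deviance)
            llf, df_resid = float(res.llf), float(res.df_resid)
        if np.any(np.abs(res.params) > 15):
            flags.append("possible separation: unbounded estimate")
        params, bse = res.params, res.bse
        cov = res.cov_params()
    elif spec.family == "gaussian-mixed":
        if spec.groups is None:
            raise SelectionError(f"{spec.name}: mixed model needs a grouping column")
        from chronest.lmm import fit_crossed_lmm

        res = fit_crossed_lmm(
            y, X, {"brood": data[spec.groups].to_numpy()}, reml=False, fixed_names=names
        )
        dev = float("nan")
        llf, df_resid = res.loglik, float(len(y) - X.shape[1])
        params, bse = res.beta, res.se
        cov = res.cov_beta
    else:
        raise SelectionError(f"unknown family {spec.family!r}")

    params = pd.Series(np.asarray(params)[: len(names)], index=names)
    bse = pd.Series(np.asarray(bse)[: len(names)], index=names)
    cov = pd.DataFrame(np.asarray(cov)[: len(names), : len(names)], index=names, columns=names)
    return ModelFit(
        spec=spec, terms=list(terms), params=params, bse=bse, cov_params=cov,
        loglik=llf, deviance=dev, df_resid=df_resid, n=len(y), flags=flags,
    )


def _deletion_test(spec: ModelSpec, full: ModelFit, term: Term) -> tuple[str, float, int, float]:
    """Single-term deletion test; returns (kind, stat, df, p).

    Binomial deviance statistics are signed as the change in deviance
    from the reduced to the full model (negative when the term
    improves the fit), matching the reporting convention for deviance
    tests; the p-value uses the magnitude.
    """
    reduced_terms = [t for t in full.terms if t != term]
    reduced = fit_model(spec, reduced_terms)
    dfree = int(round(reduced.df_resid - full.df_resid)) if spec.family != "gaussian-mixed" else None
    if spec.family == "gaussian":
        num = (reduced.deviance - full.deviance) / max(dfree, 1)
        den = full.deviance / full.df_resid
        stat = num / den if den > 0 else np.inf
        p = float(stats.f.sf(stat, max(dfree, 1), full.df_resid))
        return "F", float(stat), max(dfree, 1), p
    if spec.family == "binomial":
        delta = reduced.deviance - full.deviance
        p = float(stats.chi2.sf(max(delta, 0.0), max(dfree, 1)))
        return "Deviance", float(-delta), max(dfree, 1), p
    # mixed: ML likelihood ratio
    X_f, _, _ = build_design(full.terms, spec.data)
    X_r, _, _ = build_design(reduced_terms, spec.data)
    dfree = X_f.shape[1] - X_r.shape[1]
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, max(dfree, 1)))
    return "Chisq", float(stat), max(dfree, 1), p


def stepwise_reduce(
    spec: ModelSpec,
    alpha: float = 0.05,
    force_retain: "tuple[str, ...]" = (),
    fit: ModelFit | None = None,
) -> ModelFit:
    """Backward elimination with marginality; returns the final fit.

    The returned fit carries the full ``reduction_path``: one
    :class:`TermTest` per original term, with the deletion statistic
    and the pre-drop estimate and SE (protected terms — contained in a
    retained higher-order term — carry no test).
    """
    current = fit if fit is not None else fit_model(spec)
    path: list[TermTest] = []
    while True:
        droppable = [
            t
            for t in current.terms
            if t.powers
            and t.name not in force_retain
            and not any(o.contains(t) for o in current.terms)
        ]
        if not droppable:
            break
        tests = {t: _deletion_test(spec, current, t) for t in droppable}
        worst = max(droppable, key=lambda t: tests[t][3])
        kind, stat, dfree, p = tests[worst]
        if p >= alpha:
            path.append(TermTest(
                term=worst, kind=kind, stat=stat, df=dfree, p=p,
                estimates=current.term_estimates(worst), dropped=True,
            ))
            current = fit_model(spec, [t for t in current.terms if t != worst])
        else:
            for t in droppable:
                k2, s2, d2, p2 = tests[t]
                path.append(TermTest(
                    term=t, kind=k2, stat=s2, df=d2, p=p2,
                    estimates=current.term_estimates(t), dropped=False,
                ))
            break
    # protected survivors (no valid deletion test under marginality)
    tested = {tt.term for tt in path}
    for t in current.terms:
        if t.powers and t not in tested:
            path.append(TermTest(
                term=t, kind="", stat=np.nan, df=0, p=np.nan,
                estimates=current.term_estimates(t), dropped=False, protected=True,
            ))
    current.reduction_path = path
    return current


def reduction_table(fit: ModelFit) -> pd.DataFrame:
    """Reduction path as a tidy table (term, test, estimate, retained)."""
    rows = []
    for tt in fit.reduction_path:
        est = tt.estimates[0] if tt.estimates else (tt.term.name, np.nan, np.nan)
        rows.append({
            "term": tt.term.name,
            "kind": tt.kind,
            "stat": tt.stat,
            "df": tt.df,
            "p": tt.p,
            "estimate": est[1],
            "se": est[2],
            "retained": not tt.dropped,
            "protected": tt.protected,
        })
    return pd.DataFrame(
        rows,
        columns=["term", "kind", "stat", "df", "p", "estimate", "se", "retained", "protected"],
    )


# ---------------------------------------------------------------------------
# prediction bands


def simulate_prediction_band(
    fit: ModelFit,
    newdata: pd.DataFrame,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based point predictions with 95% bands.

    Coefficient vectors are drawn from the asymptotic multivariate
    normal of the estimates, pushed through the linear predictor and
    the inverse link; the band is the 2.5/97.5 percentile of the draws
    (2000 by default).
    """
    year_levels = (
        np.sort(fit.spec.data["year"].unique())
        if "year" in fit.spec.data.columns
        else np.array([])
    )
    X, names, _ = build_design(fit.terms, newdata, year_levels)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    cov = (cov + cov.T) / 2.0
    rng = np.random.default_rng(seed)
    if np.allclose(cov, 0.0):
        draws = np.tile(beta, (n_draws, 1))
    else:
        eigval, eigvec = np.linalg.eigh(cov)
        tol = 1e-10 * max(eigval.max(), 1.0)
        if np.any(eigval < -tol) or not np.all(np.isfinite(eigval)):
            raise SelectionError("singular or invalid coefficient covariance")
        root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        draws = beta + rng.standard_normal((n_draws, len(beta))) @ root.T
    eta = draws @ X.T
    point = X @ beta
    if fit.spec.family == "binomial":
        eta = 1.0 / (1.0 + np.exp(-eta))
        point = 1.0 / (1.0 + np.exp(-point))
    lo, hi = np.percentile(eta, [2.5, 97.5], axis=0)
    return pd.DataFrame({"predicted": point, "lower": lo, "upper": hi})
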