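"""Descriptive statistics, prevalence intervals, and sex-stratified
sequentially-adjusted logistic odds-ratio tables.

The analysis reproduced here asks whether metabolically healthy obesity
carries hyperuricemia risk once confounders are adjusted for, and whether
the answer differs by sex.  The machinery is:

* :func:`prevalence_ci` — binomial point prevalence with a Wilson score
  interval (Clopper-Pearson available);
* :func:`describe_cohort` — per-variable sex comparison (pooled-variance
  t-test for continuous fields, uncorrected Pearson chi-square for flags);
* :func:`fit_logistic` / :func:`odds_ratio_table` — maximum-likelihood
  logistic fits (Newton/IRLS via statsmodels) with Wald confidence
  intervals on the odds-ratio scale;
* :class:`AssociationModel` / :func:`run_association_models` — the two
  sequentially adjusted models (model 1: age, sex, urban residence, smoking,
  alcohol, phenotype; model 2: + white blood cell count, total cholesterol,
  LDL-C, hs-CRP, diabetes) fitted for the total sample and within each sex
  (dropping the sex term), phenotype coded as five indicators against the
  MHNW reference;
* :func:`stepwise_select` — backward elimination by AIC with the phenotype
  indicators entering and leaving as a block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .phenotypes import PHENOTYPES, Thresholds, derive_phenotypes

__all__ = [
    "PrevalenceCell",
    "LogisticFit",
    "AssociationModel",
    "AssociationResults",
    "prevalence_ci",
    "prevalence_by_phenotype",
    "describe_cohort",
    "fit_logistic",
    "odds_ratio_table",
    "run_association_models",
    "stepwise_select",
]

Z_95 = 1.959963984540054

MODEL1_TERMS = ("age", "urban", "smoker", "alcohol")
MODEL2_EXTRA = ("white_blood_cell", "tc", "ldl_c", "hs_crp", "diabetes")


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; the message names collinear terms."""


class NotConvergedError(RuntimeError):
    """A downstream summary was requested from a non-converged fit."""


@dataclass(frozen=True)
class PrevalenceCell:
    """Stratum prevalence with a confidence interval."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "wilson"
    stratum: tuple | None = None


def prevalence_ci(k: int, n: int, level: float = 0.95, method: str = "wilson",
                  stratum=None) -> PrevalenceCell:
    """Binomial prevalence k/n with a Wilson score interval.

    ``method`` may be ``"wilson"`` (default; asymmetric, good small-sample
    coverage) or ``"clopper-pearson"`` (exact beta).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"event count k={k} outside [0, n={n}]")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown interval method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    lo = 0.0 if k == 0 else float(lo)  # guard rounding artifacts at the boundary
    hi = 1.0 if k == n else float(hi)
    return PrevalenceCell(
        k=int(k), n=int(n), p_hat=k / n, ci_low=float(lo), ci_high=float(hi),
        level=level, method=method, stratum=stratum,
    )


def prevalence_by_phenotype(
    phenotyped: pd.DataFrame, outcome: str = "hyperuricemia", level: float = 0.95,
    method: str = "wilson",
) -> pd.DataFrame:
    """Sex-specific outcome prevalence per metabolic-obesity phenotype.

    One row per (phenotype, sex) cell with counts, prevalence in percent and
    the confidence bounds; ``excluded`` (underweight) records are dropped.
    """
    rows = []
    for p in PHENOTYPES:
        for sex in ("male", "female"):
            sub = phenotyped[(phenotyped["phenotype"] == p) & (phenotyped["sex"] == sex)]
            if len(sub) == 0:
                rows.append({"phenotype": p, "sex": sex, "k": 0, "n": 0,
                             "prevalence_pct": np.nan, "ci_low_pct": np.nan,
                             "ci_high_pct": np.nan})
                continue
            cell = prevalence_ci(int(sub[outcome].sum()), len(sub), level, method, (p, sex))
            rows.append({
                "phenotype": p, "sex": sex, "k": cell.k, "n": cell.n,
                "prevalence_pct": 100 * cell.p_hat,
                "ci_low_pct": 100 * cell.ci_low, "ci_high_pct": 100 * cell.ci_high,
            })
    return pd.DataFrame(rows)


_CONTINUOUS = ("age", "weight", "height", "bmi", "waist_circumference", "sbp",
               "dbp", "fpg", "tg", "hdl_c", "ldl_c", "tc", "uric_acid",
               "fasting_insulin", "hs_crp", "white_blood_cell", "homa_ir", "vai")
_CATEGORICAL = ("smoker", "alcohol", "urban", "diabetes", "hyperuricemia",
                "abdominal_obesity", "atp3_elevated_bp", "atp3_elevated_tg",
                "atp3_elevated_fpg", "atp3_reduced_hdl",
                "metabolically_healthy_atp3", "bmi_class", "phenotype")


def describe_cohort(cohort: pd.DataFrame, group: str = "sex") -> pd.DataFrame:
    """Two-group descriptive table with significance tests.

    Continuous fields get group means +/- SD and a pooled-variance Student
    t-test; categorical fields get counts (percent) and an uncorrected
    Pearson chi-square test.  A zero-variance continuous field is reported
    with an undefined test (NaN) and a warning.
    """
    levels = sorted(pd.unique(cohort[group]))
    if len(levels) != 2:
        raise ValueError(f"grouping variable {group!r} must have exactly 2 levels, got {levels}")
    g1 = cohort[cohort[group] == levels[0]]
    g2 = cohort[cohort[group] == levels[1]]
    rows = []
    for c in cohort.columns:
        if c in (group, "id"):
            continue
        if c in _CONTINUOUS and c in cohort.columns:
            x, y = g1[c].to_numpy(float), g2[c].to_numpy(float)
            if np.var(x) == 0 and np.var(y) == 0:
                warnings.warn(f"zero variance in {c!r}; t-test undefined", stacklevel=2)
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            rows.append({
                "variable": c, "kind": "continuous",
                f"{levels[0]}": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                f"{levels[1]}": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                "statistic": float(t), "p_value": float(p),
            })
        elif c in _CATEGORICAL:
            tab = pd.crosstab(cohort[group], cohort[c])
            if tab.shape[1] < 2:
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            def fmt(g):
                v = g[c]
                top = v.value_counts().index[0] if c not in ("smoker", "alcohol", "urban",
                                                             "diabetes", "hyperuricemia") else 1
                k = int((v == top).sum())
                return f"{k} ({100 * k / len(v):.1f}%)"
            rows.append({
                "variable": c, "kind": "categorical",
                f"{levels[0]}": fmt(g1), f"{levels[1]}": fmt(g2),
                "statistic": float(stat) if stat == stat else np.nan,
                "p_value": float(p) if p == p else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``params``/``cov`` are indexed by term name; ``converged`` is False for
    non-convergence or (quasi-)separation; ``diagnostic`` explains why.
    """

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    n: int
    diagnostic: str = ""

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.llf


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if np.any(np.all(arr == 0, axis=0)):
        bad = [c for c in X.columns if np.all(X[c].to_numpy(float) == 0)]
        raise RankDeficientError(f"constant-zero column(s): {bad}")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the dependent columns via pivoted QR
        _, r, piv = stats_qr(arr)
        bad = sorted(X.columns[j] for j in piv[rank:])
        raise RankDeficientError(f"linearly dependent term(s): {bad}")


def stats_qr(arr):
    from scipy.linalg import qr

    q, r, piv = qr(arr, pivoting=True, mode="economic")
    return q, r, piv


def fit_logistic(design: pd.DataFrame, outcome, maxiter: int = 50, tol: float = 1e-8) -> LogisticFit:
    """Fit a binary logistic model by Newton iteration (IRLS).

    ``design`` is the named predictor matrix (include an intercept column
    explicitly if wanted); ``outcome`` a 0/1 vector.  Convergence requires
    the maximum absolute score below ``tol`` within ``maxiter`` iterations;
    the covariance is the inverse observed information.  Separation
    (divergent coefficients) yields ``converged=False`` with a diagnostic
    rather than an exception; a rank-deficient design raises
    :class:`RankDeficientError` naming the collinear terms.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    _check_rank(design)
    X = design.to_numpy(float)
    model = sm.Logit(y, X)
    diagnostic = ""
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0,
                            warn_convergence=False)
        except Exception as e:  # statsmodels raises on perfect separation
            return LogisticFit(
                params=pd.Series(np.nan, index=design.columns),
                cov=pd.DataFrame(np.nan, index=design.columns, columns=design.columns),
                llf=np.nan, converged=False, n=len(y),
                diagnostic=f"fit failed: {e}",
            )
    score = model.score(res.params)
    if not np.all(np.abs(score) < 1e-6):
        converged = False
        diagnostic = f"max |score| = {np.max(np.abs(score)):.3g} after {maxiter} iterations"
    if np.any(np.abs(res.params) > 20):
        converged = False
        diagnostic = (diagnostic + "; " if diagnostic else "") + \
            "coefficient magnitude > 20 suggests (quasi-)separation"
    return LogisticFit(
        params=pd.Series(res.params, index=design.columns),
        cov=pd.DataFrame(res.cov_params(), index=design.columns, columns=design.columns),
        llf=float(res.llf), converged=converged, n=len(y), diagnostic=diagnostic,
    )


def odds_ratio_table(fit: LogisticFit, terms: list[str] | None = None, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald confidence intervals for selected terms.

    OR = exp(beta); CI = exp(beta +/- z * SE).  Refuses a non-converged fit.
    """
    if not fit.converged:
        raise NotConvergedError(f"fit did not converge: {fit.diagnostic}")
    terms = list(terms) if terms is not None else [t for t in fit.params.index if t != "const"]
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for t in terms:
        b, se = fit.params[t], fit.bse[t]
        rows.append({"term": t, "or": float(np.exp(b)),
                     "ci_low": float(np.exp(b - z * se)),
                     "ci_high": float(np.exp(b + z * se))})
    return pd.DataFrame(rows)


def _phenotype_design(df: pd.DataFrame, terms: tuple[str, ...], include_sex: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for t in terms:
        X[t] = df[t].astype(float)
    if include_sex:
        X["sex_female"] = (df["sex"] == "female").astype(float)
    for p in PHENOTYPES[1:]:
        X[f"phenotype_{p}"] = (df["phenotype"] == p).astype(float)
    return X


def run_association_models(cohort: pd.DataFrame, thresholds: Thresholds | None = None,
                           level: float = 0.95) -> pd.DataFrame:
    """The full sequentially-adjusted, sex-stratified odds-ratio table.

    Fits model 1 (age, sex, urban, smoking, alcohol + phenotype) and model 2
    (model 1 + white blood cell, total cholesterol, LDL-C, hs-CRP, diabetes)
    on the total sample and within each sex (no sex term), with phenotype as
    five indicators against MHNW.  Returns one row per
    (stratum, model, phenotype) including the reference rows (OR exactly 1).
    A phenotype level empty within a stratum yields an undefined-OR row and
    a warning.
    """
    df = cohort
    if "phenotype" not in df.columns:
        df = derive_phenotypes(df, thresholds)
    df = df[df["phenotype"] != "excluded"]
    occupied = df["phenotype"].nunique()
    if occupied < 2:
        raise ValueError("phenotype must have at least 2 occupied levels")
    rows = []
    strata = {"total": df, "men": df[df["sex"] == "male"], "women": df[df["sex"] == "female"]}
    for stratum, sub in strata.items():
        for model_id, terms in ((1, MODEL1_TERMS), (2, MODEL1_TERMS + MODEL2_EXTRA)):
            if len(sub) == 0:
                warnings.warn(f"stratum {stratum!r} is empty; all its odds ratios are "
                              "undefined", stacklevel=2)
                for p in PHENOTYPES:
                    rows.append({"stratum": stratum, "model": model_id, "phenotype": p,
                                 "or": 1.0 if p == "MHNW" else np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan,
                                 "reference": p == "MHNW"})
                continue
            empty = [p for p in PHENOTYPES if (sub["phenotype"] == p).sum() == 0]
            if empty:
                warnings.warn(
                    f"empty phenotype cell(s) {empty} in stratum {stratum!r}; "
                    "their odds ratios are undefined", stacklevel=2,
                )
            X = _phenotype_design(
                sub, terms, include_sex=(stratum == "total" and sub["sex"].nunique() == 2)
            )
            X = X.drop(columns=[f"phenotype_{p}" for p in empty if p != "MHNW"], errors="ignore")
            fit = fit_logistic(X, sub["hyperuricemia"])
            if fit.converged:
                ors = odds_ratio_table(
                    fit, [c for c in X.columns if c.startswith("phenotype_")], level
                ).set_index("term")
            else:
                ors = pd.DataFrame()
            for p in PHENOTYPES:
                if p == "MHNW":
                    rows.append({"stratum": stratum, "model": model_id, "phenotype": p,
                                 "or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                                 "reference": True})
                    continue
                key = f"phenotype_{p}"
                if p in empty or not fit.converged or key not in ors.index:
                    rows.append({"stratum": stratum, "model": model_id, "phenotype": p,
                                 "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "reference": False})
                else:
                    r = ors.loc[key]
                    rows.append({"stratum": stratum, "model": model_id, "phenotype": p,
                                 "or": r["or"], "ci_low": r["ci_low"],
                                 "ci_high": r["ci_high"], "reference": False})
    return pd.DataFrame(rows)


@dataclass
class AssociationResults:
    """Fitted association models: the tidy odds-ratio table plus raw fits."""

    or_table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Sex-stratified phenotype odds ratios for hyperuricemia",
                 "(reference: MHNW; Wald 95% CI)", ""]
        for stratum in ("total", "men", "women"):
            lines.append(f"--- {stratum} ---")
            lines.append(f"{'phenotype':<10}{'model 1':>22}{'model 2':>22}")
            sub = self.or_table[self.or_table["stratum"] == stratum]
            for p in PHENOTYPES:
                cells = []
                for m in (1, 2):
                    r = sub[(sub["model"] == m) & (sub["phenotype"] == p)].iloc[0]
                    if r["reference"]:
                        cells.append("1 (reference)")
                    elif np.isnan(r["or"]):
                        cells.append("undefined")
                    else:
                        cells.append(f"{r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
                lines.append(f"{p:<10}{cells[0]:>22}{cells[1]:>22}")
            lines.append("")
        return "\n".join(lines)


class AssociationModel:
    """Model object for the phenotype-hyperuricemia association analysis.

    Construct from a raw or phenotyped cohort table; :meth:`fit` runs both
    adjustment models in all three sex strata and returns
    :class:`AssociationResults`.
    """

    def __init__(self, cohort: pd.DataFrame, thresholds: Thresholds | None = None):
        self.thresholds = thresholds or Thresholds()
        self.cohort = (
            cohort if "phenotype" in cohort.columns else derive_phenotypes(cohort, self.thresholds)
        )

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "AssociationModel":
        return cls(cohort, **kwargs)

    def fit(self, level: float = 0.95) -> AssociationResults:
        table = run_association_models(self.cohort, self.thresholds, level)
        return AssociationResults(or_table=table)


def stepwise_select(
    design: pd.DataFrame,
    outcome,
    candidates: list[str],
    blocks: dict[str, list[str]] | None = None,
) -> tuple[list[str], LogisticFit]:
    """Backward elimination by AIC with optional term blocks.

    Starts from the full model (``const`` plus all candidates) and
    repeatedly removes the candidate — or whole block, e.g. the five
    phenotype indicators — whose removal lowers AIC the most, until no
    removal improves AIC.  Deterministic: ties are broken by the candidate
    order given.  Returns the retained terms and the final fit.
    """
    if not candidates:
        raise ValueError("at least one candidate term is required")
    blocks = blocks or {}
    in_block = {t: name for name, ts in blocks.items() for t in ts}
    units: list[tuple[str, list[str]]] = []
    seen = set()
    for t in candidates:
        b = in_block.get(t)
        if b is None:
            units.append((t, [t]))
        elif b not in seen:
            seen.add(b)
            units.append((b, blocks[b]))
    current = list(units)

    def fit_for(unit_list):
        cols = ["const"] + [t for _, ts in unit_list for t in ts]
        return fit_logistic(design[cols], outcome)

    best_fit = fit_for(current)
    improved = True
    while improved and current:
        improved = False
        best_drop, best_aic, best_drop_fit = None, best_fit.aic, None
        for i, unit in enumerate(current):
            trial = current[:i] + current[i + 1:]
            f = fit_for(trial)
            if f.converged and f.aic < best_aic - 1e-12:
                best_drop, best_aic, best_drop_fit = i, f.aic, f
        if best_drop is not None:
            current.pop(best_drop)
            best_fit = best_drop_fit
            improved = True
    retained = [t for _, ts in current for t in ts]
    return retained, best_fit
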