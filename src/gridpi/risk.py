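"""Cohort risk statistics for the path-integration outcomes.

Implements the statistical layer relating triangle-completion performance
to dementia risk factors: trial-level linear mixed models, change-score
(condition-minus-baseline) interaction regressions with Tukey-corrected
cell contrasts, nested model comparison, cross-validated elastic-net risk
classification, Johnson-Neyman interaction probing, and Benjamini-Hochberg
FDR correction.

Risk factors: parental family history of dementia (``fh``, 0/1), APOE e4
carriage (``apoe4``, 0/1), the CAIDE dementia risk score (``caide``, 0-15,
always modeled continuously), and ``sex`` (F/M). CAIDE already incorporates
age, sex and education, so CAIDE-univariate models must not co-adjust for
them; this is enforced structurally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fit_trial_mixed",
    "fit_change_regression",
    "caide_univariate_regression",
    "check_caide_covariates",
    "tukey_cell_contrasts",
    "compare_nested",
    "double_risk_label",
    "elasticnet_risk_auc",
    "johnson_neyman",
    "fdr_correct",
    "median_split",
    "MixedTrialResults",
    "ChangeRegressionResults",
    "ElasticNetRiskResults",
    "JohnsonNeymanResult",
]

RISK_FACTORS = ("fh", "apoe4", "caide")
CAIDE_FORBIDDEN_COVARIATES = ("age_y", "edu_y", "sex")


def check_caide_covariates(risk_terms, covariates) -> None:
    """Enforce the CAIDE covariate rule.

    The CAIDE score already contains age, sex and education, so a model in
    which CAIDE is the only risk factor must not co-adjust for any of them.
    Raises ``ValueError`` on violation.
    """
    risk = {t for term in risk_terms for t in str(term).split(":")}
    if risk & set(RISK_FACTORS) == {"caide"}:
        bad = [c for c in covariates if c in CAIDE_FORBIDDEN_COVARIATES]
        if bad:
            raise ValueError(
                "CAIDE-univariate models must not adjust for "
                f"{bad}: these variables are part of the CAIDE score"
            )


# ---------------------------------------------------------------------------
# trial-level mixed model
# ---------------------------------------------------------------------------


@dataclass
class MixedTrialResults:
    """Fitted trial-level mixed model with per-term Wald tests."""

    results: object  # statsmodels MixedLMResults
    anova: pd.DataFrame
    formula: str
    random_structure: str
    fell_back: bool

    def summary(self):
        return self.results.summary()

    def residual_diagnostics(self) -> dict:
        """Shapiro normality and a Breusch-Pagan-style het check on residuals."""
        resid = np.asarray(self.results.resid)
        resid = resid[np.isfinite(resid)]
        sub = resid if resid.size <= 4000 else resid[:: resid.size // 4000 + 1]
        w, p_norm = stats.shapiro(sub)
        fitted = np.asarray(self.results.fittedvalues)[np.isfinite(resid)]
        r, p_het = stats.spearmanr(np.abs(resid), fitted[: resid.size])
        return {
            "shapiro_w": float(w),
            "shapiro_p": float(p_norm),
            "abs_resid_vs_fitted_rho": float(r),
            "abs_resid_vs_fitted_p": float(p_het),
        }


def fit_trial_mixed(
    trials: pd.DataFrame,
    outcome: str = "location_error",
    fixed: str = "fh * C(condition) * sex + apoe4 * C(condition) * sex "
    "+ caide * C(condition) + age_y + edu_y",
    random_slope: bool = True,
    trial_order_intercept: bool = True,
) -> MixedTrialResults:
    """Trial-level mixed model of an error statistic on risk x condition x sex.

    Random structure: participant random intercepts with return-condition
    random slopes, plus trial-order intercepts as a variance component
    (entered within participant; the fully crossed design is outside
    statsmodels' single-grouping mixed models). On a singular or
    non-converged fit the model falls back to participant intercepts only,
    with a warning.

    Requires >= 2 participants and >= 2 conditions in ``trials`` (tidy
    per-trial rows joined with the participant table).
    """
    data = trials.dropna(subset=[outcome]).copy()
    if data["pid"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    if data["condition"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 conditions represented")
    formula = f"{outcome} ~ {fixed}"
    vc = (
        {"trial_order": "0 + C(trial)"}
        if trial_order_intercept and "trial" in data
        else None
    )
    re_formula = "~C(condition)" if random_slope else "1"

    from patsy import dmatrix

    fixed_mat = np.asarray(dmatrix(fixed, data))
    if np.linalg.matrix_rank(fixed_mat) < fixed_mat.shape[1]:
        raise ValueError(
            "singular fixed-effects design (empty risk-factor cells); "
            "reduce the interaction order or enlarge the cohort"
        )

    def _fit(re_f, vc_f):
        model = smf.mixedlm(
            formula, data, groups=data["pid"], re_formula=re_f, vc_formula=vc_f
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True)

    fell_back = False
    structure = f"re={re_formula}" + (", vc=trial_order" if vc else "")
    try:
        res = _fit(re_formula, vc)
        singular = not np.all(np.isfinite(res.bse_fe)) or not res.converged
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        res = None
    if singular:
        warnings.warn(
            "singular or non-converged random-effects fit; falling back to "
            "participant random intercepts only",
            stacklevel=2,
        )
        fell_back = True
        structure = "re=1 (fallback)"
        try:
            res = _fit("1", None)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "mixed model could not be fit (near-singular design)"
            ) from exc
    anova = _wald_term_table(res)
    return MixedTrialResults(res, anova, formula, structure, fell_back)


def _wald_term_table(res) -> pd.DataFrame:
    """Per-term Wald F tests for the fixed effects of a mixed fit.

    For each formula term, F = b' V^-1 b / q over the term's coefficients,
    referred to F(q, n - k_fe). (A simple residual-style denominator df;
    no Satterthwaite correction.)
    """
    fe = res.fe_params
    V = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    design_info = res.model.data.design_info
    n_obs = res.model.nobs if np.isscalar(res.model.nobs) else len(res.model.endog)
    df_den = max(int(n_obs) - len(fe), 1)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        idx = np.arange(len(fe))[sl]
        if idx.size == 0:  # single-level factor: term contributes no columns
            continue
        b = np.asarray(fe)[idx]
        Vs = V[np.ix_(idx, idx)]
        q = len(idx)
        try:
            stat = float(b @ np.linalg.solve(Vs, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        f_stat = stat / q
        rows.append(
            {
                "term": term,
                "F": f_stat,
                "df": q,
                "df_den": df_den,
                "p": float(stats.f.sf(f_stat, q, df_den))
                if np.isfinite(f_stat)
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# change-score regressions + Tukey cell contrasts
# ---------------------------------------------------------------------------


@dataclass
class ChangeRegressionResults:
    """OLS change-score model with ANOVA table and Tukey cell contrasts."""

    results: object  # statsmodels OLSResults
    anova: pd.DataFrame
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    formula: str

    def summary(self):
        return self.results.summary()

    @property
    def adj_r2(self) -> float:
        return float(self.results.rsquared_adj)


def fit_change_regression(
    cohort: pd.DataFrame,
    outcome: str,
    risk_formula: str = "fh * apoe4 * caide * sex",
    covariates: tuple = ("age_y", "edu_y"),
    contrast_factors: tuple = ("fh", "apoe4", "sex"),
) -> ChangeRegressionResults:
    """Regression of a baseline-referenced change score on risk interactions.

    ``outcome`` is a per-participant change score (e.g. ``delta_CA``, the
    no-distal-cues minus baseline mean location error). The default model
    is the full risk interaction fh x apoe4 x caide x sex plus age and
    education covariates; ANOVA (type II) F tests per term, and Tukey-
    corrected pairwise contrasts of the estimated marginal means over the
    ``contrast_factors`` cells (computed at covariate means). Rows with a
    missing outcome are dropped listwise.
    """
    check_caide_covariates(_formula_terms(risk_formula), covariates)
    rhs = risk_formula if not covariates else f"{risk_formula} + " + " + ".join(covariates)
    formula = f"{outcome} ~ {rhs}"
    data = cohort.dropna(subset=[outcome]).copy()
    res = smf.ols(formula, data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(res, typ=2)
    if np.var(data[outcome].to_numpy(float)) == 0.0:
        # degenerate constant outcome: all effects are exactly null
        anova.loc[anova.index != "Residual", "F"] = 0.0
        anova.loc[anova.index != "Residual", "PR(>F)"] = 1.0
    emmeans, contrasts = tukey_cell_contrasts(res, data, contrast_factors)
    return ChangeRegressionResults(res, anova, emmeans, contrasts, formula)


def caide_univariate_regression(
    cohort: pd.DataFrame, outcome: str
) -> ChangeRegressionResults:
    """CAIDE-only change-score model (no age/sex/education covariates)."""
    return fit_change_regression(
        cohort, outcome, risk_formula="caide", covariates=(), contrast_factors=()
    )


def _formula_terms(risk_formula: str):
    out = []
    for chunk in risk_formula.replace("*", "+").split("+"):
        chunk = chunk.strip()
        if chunk:
            out.append(chunk)
    return out


def tukey_cell_contrasts(res, data: pd.DataFrame, factors: tuple):
    """Estimated marginal means and Tukey-Kramer pairwise contrasts.

    Builds one prediction row per cell of the factor grid with all other
    model variables at their sample means, then compares cells pairwise
    with t statistics referred to the studentized-range distribution
    (family size = number of non-empty cells). Cells absent from the data
    are reported as missing and excluded from the family.
    """
    if not factors:
        return pd.DataFrame(), pd.DataFrame()
    design_info = res.model.data.design_info
    levels = [sorted(data[f].dropna().unique()) for f in factors]
    numeric = data.select_dtypes(include=[np.number]).mean()
    cells, rows, empty = [], [], []
    for combo in itertools.product(*levels):
        cell = dict(zip(factors, combo))
        present = np.ones(len(data), dtype=bool)
        for f, v in cell.items():
            present &= (data[f] == v).to_numpy()
        if not present.any():
            empty.append(cell)
            continue
        ref = {c: [numeric[c]] for c in numeric.index if c in data.columns}
        for c in data.columns:
            if c not in ref and c not in cell and data[c].dtype == object:
                ref[c] = [data[c].mode().iloc[0]]
        for f, v in cell.items():
            ref[f] = [v]
        (X,) = build_design_matrices([design_info], pd.DataFrame(ref))
        cells.append(cell)
        rows.append(np.asarray(X)[0])
    if not cells:
        return pd.DataFrame(), pd.DataFrame()
    L = np.vstack(rows)
    beta = np.asarray(res.params)
    V = np.asarray(res.cov_params())
    means = L @ beta
    k, df = len(cells), int(res.df_resid)
    label = [
        "/".join(f"{f}={v}" for f, v in cell.items()) for cell in cells
    ]
    emmeans = pd.DataFrame(
        {
            "cell": label,
            "emmean": means,
            "se": np.sqrt(np.einsum("ij,jk,ik->i", L, V, L)),
        }
    )
    out = []
    for i, j in itertools.combinations(range(k), 2):
        d = L[i] - L[j]
        est = float(d @ beta)
        se = float(np.sqrt(d @ V @ d))
        t = est / se if se > 0 else 0.0
        q = abs(t) * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df)) if se > 0 else 1.0
        out.append(
            {"cell_1": label[i], "cell_2": label[j], "estimate": est,
             "se": se, "t": t, "p_tukey": min(p, 1.0)}
        )
    for cell in empty:
        out.append(
            {"cell_1": "/".join(f"{f}={v}" for f, v in cell.items()),
             "cell_2": None, "estimate": np.nan, "se": np.nan,
             "t": np.nan, "p_tukey": np.nan}
        )
    return emmeans, pd.DataFrame(out)


# ---------------------------------------------------------------------------
# nested model comparison
# ---------------------------------------------------------------------------


def compare_nested(full: ChangeRegressionResults, reduced: dict) -> pd.DataFrame:
    """Incremental F tests of reduced models against the full model.

    ``reduced`` maps a label to a fitted :class:`ChangeRegressionResults`
    whose design columns are a subset of the full model's. Returns a table
    of incremental F, p and both adjusted R-squared values.
    """
    f_res = full.results
    full_cols = set(f_res.model.exog_names)
    rows = []
    for name, red in reduced.items():
        r_res = red.results
        extra = set(r_res.model.exog_names) - full_cols
        if extra:
            raise ValueError(
                f"model {name!r} is not nested in the full model "
                f"(extra columns {sorted(extra)})"
            )
        df_diff = r_res.df_resid - f_res.df_resid
        if df_diff == 0:
            f_stat, p = 0.0, 1.0
        else:
            num = (r_res.ssr - f_res.ssr) / df_diff
            den = f_res.ssr / f_res.df_resid
            f_stat = float(max(num / den, 0.0))
            p = float(stats.f.sf(f_stat, df_diff, f_res.df_resid))
        rows.append(
            {
                "model": name,
                "F": f_stat,
                "df_num": int(df_diff),
                "df_den": int(f_res.df_resid),
                "p": p,
                "adj_r2_reduced": float(r_res.rsquared_adj),
                "adj_r2_full": float(f_res.rsquared_adj),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elastic-net risk classification
# ---------------------------------------------------------------------------


def double_risk_label(cohort: pd.DataFrame) -> pd.Series:
    """The double-risk classification target: FH+ and APOE e4+ vs. rest."""
    return ((cohort["fh"] == 1) & (cohort["apoe4"] == 1)).astype(int)


@dataclass
class ElasticNetRiskResults:
    """Permutation-averaged elastic-net classification performance."""

    mean_auc: float
    aucs: np.ndarray
    selection_frequency: pd.Series  # % of permutations with non-zero coef
    n_permutations: int
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"elastic-net risk classifier, {self.n_permutations} permutations",
            f"mean test AUC = {self.mean_auc:.3f}",
            "feature selection frequency (% non-zero):",
        ]
        for name, pct in self.selection_frequency.sort_values(ascending=False).items():
            lines.append(f"  {name:24s} {pct:6.1f}%")
        return "\n".join(lines)


def elasticnet_risk_auc(
    features: pd.DataFrame,
    label: pd.Series,
    n_permutations: int = 1000,
    test_size: float = 0.3,
    l1_ratios=(0.1, 0.5, 0.9, 1.0),
    Cs: int = 5,
    inner_cv: int = 5,
    seed=None,
    max_resample: int = 200,
) -> ElasticNetRiskResults:
    """Cross-validated elastic-net logistic classification of risk status.

    Per permutation: a random train/test split (70/30 by default), inner CV
    on the training set selecting the penalty to maximize ROC AUC, then the
    held-out test AUC. Splits leaving fewer than 3 positives (or no
    negatives) in the test set are resampled. Reports the mean AUC and the
    percentage of permutations in which each feature kept a non-zero
    coefficient at the selected penalty.
    """
    X = pd.get_dummies(features, drop_first=True).astype(float)
    y = np.asarray(label).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("features and label must align")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_test = max(int(round(test_size * n)), 1)
    aucs = np.empty(n_permutations)
    nonzero = np.zeros(X.shape[1])
    resampled = 0
    values = X.to_numpy()
    for it in range(n_permutations):
        for _ in range(max_resample):
            idx = rng.permutation(n)
            test, train = idx[:n_test], idx[n_test:]
            if (
                y[test].sum() >= 3
                and (1 - y[test]).sum() >= 1
                and 0 < y[train].sum() < train.size
            ):
                break
            resampled += 1
        else:
            raise ValueError("could not find a usable train/test split")
        mu, sd = values[train].mean(axis=0), values[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (values[train] - mu) / sd, (values[test] - mu) / sd
        clf = LogisticRegressionCV(
            penalty="elasticnet",
            solver="saga",
            l1_ratios=list(l1_ratios),
            Cs=Cs,
            cv=min(inner_cv, int(y[train].sum()), int((1 - y[train]).sum())),
            scoring="roc_auc",
            max_iter=2000,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, y[train])
        aucs[it] = roc_auc_score(y[test], clf.decision_function(Xte))
        nonzero += np.abs(clf.coef_[0]) > 1e-10
    if resampled:
        warnings.warn(f"resampled {resampled} degenerate split(s)", stacklevel=2)
    freq = pd.Series(100.0 * nonzero / n_permutations, index=X.columns)
    return ElasticNetRiskResults(
        mean_auc=float(aucs.mean()),
        aucs=aucs,
        selection_frequency=freq,
        n_permutations=n_permutations,
        config={
            "test_size": test_size,
            "l1_ratios": list(l1_ratios),
            "Cs": Cs,
            "inner_cv": inner_cv,
        },
    )


# ---------------------------------------------------------------------------
# Johnson-Neyman interval
# ---------------------------------------------------------------------------


@dataclass
class JohnsonNeymanResult:
    """Moderator values where the focal conditional slope is significant."""

    intervals: list  # list of (lo, hi) within the moderator range
    moderator_range: tuple
    alpha: float

    @property
    def empty(self) -> bool:
        return not self.intervals

    @property
    def full(self) -> bool:
        if len(self.intervals) != 1:
            return False
        (lo, hi), (a, b) = self.intervals[0], self.moderator_range
        return np.isclose(lo, a) and np.isclose(hi, b)


def johnson_neyman(
    res,
    focal: str,
    moderator: str,
    alpha: float = 0.05,
    moderator_values: np.ndarray | None = None,
) -> JohnsonNeymanResult:
    """Johnson-Neyman significance region for a continuous interaction.

    For a model containing ``focal``, ``moderator`` and their interaction,
    returns the moderator range(s) over which the conditional slope of the
    focal predictor differs from zero at level ``alpha`` (CI excludes 0).
    The region is intersected with the observed moderator range.
    """
    names = list(res.params.index)
    inter = None
    for name in names:
        parts = set(name.split(":"))
        if parts == {focal, moderator}:
            inter = name
            break
    if inter is None:
        raise ValueError(
            f"model has no {focal} x {moderator} interaction term"
        )
    if moderator_values is None:
        moderator_values = np.asarray(res.model.data.frame[moderator], dtype=float)
    moderator_values = np.asarray(moderator_values, dtype=float)
    if np.unique(moderator_values[np.isfinite(moderator_values)]).size < 2:
        raise ValueError("moderator must take at least two distinct values")
    lo_m, hi_m = float(np.nanmin(moderator_values)), float(np.nanmax(moderator_values))

    b1 = float(res.params[focal])
    b3 = float(res.params[inter])
    V = res.cov_params()
    v11 = float(V.loc[focal, focal])
    v33 = float(V.loc[inter, inter])
    v13 = float(V.loc[focal, inter])
    tcrit = float(stats.t.ppf(1 - alpha / 2, res.df_resid))

    # slope(m)^2 - tcrit^2 * var(m) > 0  <=>  a m^2 + b m + c > 0
    a = b3**2 - tcrit**2 * v33
    b = 2 * (b1 * b3 - tcrit**2 * v13)
    c = b1**2 - tcrit**2 * v11

    def positive_region():
        if abs(a) < 1e-300:
            if abs(b) < 1e-300:
                return [(-np.inf, np.inf)] if c > 0 else []
            root = -c / b
            return [(root, np.inf)] if b > 0 else [(-np.inf, root)]
        disc = b**2 - 4 * a * c
        if disc <= 0:
            return [(-np.inf, np.inf)] if a > 0 else []
        r1, r2 = sorted(
            [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        )
        if a > 0:
            return [(-np.inf, r1), (r2, np.inf)]
        return [(r1, r2)]

    intervals = []
    for lo, hi in positive_region():
        lo, hi = max(lo, lo_m), min(hi, hi_m)
        if lo < hi:
            intervals.append((float(lo), float(hi)))
    return JohnsonNeymanResult(intervals, (lo_m, hi_m), alpha)


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def fdr_correct(pvalues, groups=None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, within each stated family.

    ``groups`` (optional) assigns each p-value to a correction family;
    adjustment is applied separately per family. Raises on empty input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot FDR-correct an empty p-value family")
    if groups is None:
        return multipletests(p, method="fdr_bh")[1]
    groups = np.asarray(groups)
    out = np.empty_like(p)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def median_split(values: pd.Series) -> pd.Series:
    """Above/below-median grouping (used for the CAIDE OOB-rate analysis)."""
    med = values.median()
    return pd.Series(
        np.where(values > med, "above", "below"), index=values.index
    )
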