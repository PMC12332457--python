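"""Cohort-level statistics: frailty classification, normality-gated
correlations, Kruskal-Wallis with Dunn post hoc contrasts, linear regression
on the word-list-memory score, and multinomial logistic frailty models.

The three-level social frailty outcome always uses the robust group as the
reference.  All models are complete-case; dropped rows are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import QUESTIONNAIRE_ITEMS

logger = logging.getLogger(__name__)

GROUP_ORDER = ["robust", "prefrail", "frail"]
_PAIRS = [("robust", "prefrail"), ("robust", "frail"), ("prefrail", "frail")]
_SEPARATION_BETA = 15.0


def classify_frailty(items) -> tuple[float, str | None]:
    """Social frailty index: score = sum of the five items; 0 -> robust,
    1 -> prefrail, 2-5 -> frail.  A missing item yields a missing class."""
    if isinstance(items, dict):
        values = [items[k] for k in QUESTIONNAIRE_ITEMS]
    else:
        values = list(items)
    if len(values) != 5:
        raise ValueError("expected exactly five frailty items")
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        return np.nan, None
    score = float(arr.sum())
    group = "robust" if score == 0 else ("prefrail" if score == 1 else "frail")
    return score, group


def classify_frailty_table(questionnaire: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; returns participant_id, score, group."""
    out = []
    for _, row in questionnaire.iterrows():
        score, group = classify_frailty([row[k] for k in QUESTIONNAIRE_ITEMS])
        out.append((row["participant_id"], score, group))
    df = pd.DataFrame(out, columns=["participant_id", "score", "group"])
    df["group"] = pd.Categorical(df["group"], categories=GROUP_ORDER)
    return df


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame  # "pearson" | "spearman" per cell
    normal: dict[str, bool]


def correlation_matrix(
    features: pd.DataFrame,
    variables: list[str] | None = None,
    gate_alpha: float = 0.05,
    min_pairs: int = 4,
) -> CorrelationMatrix:
    """Pairwise-complete correlations, Shapiro-Wilk gated.

    Pearson only where *both* variables pass the Shapiro-Wilk normality test
    at ``gate_alpha``; Spearman otherwise.  Cells with a constant variable
    or fewer than ``min_pairs`` complete pairs are missing.
    """
    variables = variables or [c for c in features.columns if features[c].dtype.kind in "fi"]
    normal: dict[str, bool] = {}
    for v in variables:
        x = features[v].dropna().to_numpy()
        if len(x) < 3 or np.ptp(x) == 0:
            normal[v] = False
            continue
        normal[v] = stats.shapiro(x).pvalue > gate_alpha
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    method = np.full((k, k), "", dtype=object)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables[: i + 1]):
            sub = features[[a, b]].dropna()
            if len(sub) < min_pairs:
                continue
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            use_pearson = normal[a] and normal[b]
            if i == j:
                rr, pp = 1.0, 0.0
            elif use_pearson:
                rr, pp = stats.pearsonr(x, y)
            else:
                rr, pp = stats.spearmanr(x, y)
            m = "pearson" if use_pearson else "spearman"
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
            method[i, j] = method[j, i] = m
    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        method=pd.DataFrame(method, index=idx, columns=idx),
        normal=normal,
    )


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> dict[tuple, tuple]:
    """Dunn z tests on joint ranks with tie correction; returns per-pair
    (z, raw p, Bonferroni-adjusted p) with a factor of 3 (three contrasts)."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    out = {}
    for a, b in _PAIRS:
        ia, ib = labels == a, labels == b
        na, nb = int(ia.sum()), int(ib.sum())
        if na == 0 or nb == 0:
            out[(a, b)] = (np.nan, np.nan, np.nan)
            continue
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        if se == 0:
            out[(a, b)] = (0.0, 1.0, 1.0)
            continue
        z = (ranks[ia].mean() - ranks[ib].mean()) / se
        praw = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = (float(z), float(praw), float(min(1.0, 3.0 * praw)))
    return out


@dataclass
class GroupTestResult:
    variable: str
    medians: dict[str, float]
    iqrs: dict[str, float]
    h_statistic: float
    p_overall: float
    pairwise_p: dict[tuple, float]       # Bonferroni-adjusted
    pairwise_p_raw: dict[tuple, float] = field(default_factory=dict)


def kruskal_dunn(
    features: pd.DataFrame,
    groups: pd.Series,
    variables: list[str] | None = None,
) -> list[GroupTestResult]:
    """Kruskal-Wallis (tie-corrected) plus Dunn post hoc contrasts for each
    variable; p values for the three pairwise contrasts are Bonferroni
    multiplied by 3 and capped at 1.  Variables with a group of fewer than
    2 observations are skipped with a logged reason."""
    variables = variables or [c for c in features.columns if features[c].dtype.kind in "fi"]
    labels = groups.astype(str).to_numpy()
    results = []
    for v in variables:
        vals = features[v].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        vals_ok, labels_ok = vals[ok], labels[ok]
        samples = [vals_ok[labels_ok == g] for g in GROUP_ORDER]
        sizes = [len(s) for s in samples]
        if sum(n > 0 for n in sizes) < 2 or any(0 < n < 2 for n in sizes):
            logger.info("kruskal_dunn: skipping %s (group sizes %s)", v, sizes)
            continue
        present = [s for s in samples if len(s)]
        try:
            with np.errstate(invalid="ignore"):
                h, p = stats.kruskal(*present)
            if np.isnan(h):  # all values identical: no evidence against H0
                h, p = 0.0, 1.0
        except ValueError:
            h, p = 0.0, 1.0
        pw = _dunn_pairwise(vals_ok, labels_ok)
        results.append(
            GroupTestResult(
                variable=v,
                medians={g: float(np.median(s)) if len(s) else np.nan
                         for g, s in zip(GROUP_ORDER, samples)},
                iqrs={g: float(np.subtract(*np.percentile(s, [75, 25]))) if len(s) else np.nan
                      for g, s in zip(GROUP_ORDER, samples)},
                h_statistic=float(h),
                p_overall=float(p),
                pairwise_p={k: adj for k, (_, _, adj) in pw.items()},
                pairwise_p_raw={k: raw for k, (_, raw, _) in pw.items()},
            )
        )
    return results


def group_tests_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"variable": r.variable, "H": r.h_statistic, "p_overall": r.p_overall}
        for g in GROUP_ORDER:
            row[f"median_{g}"] = r.medians[g]
            row[f"iqr_{g}"] = r.iqrs[g]
        for (a, b), padj in r.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = padj
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionTable:
    model_id: str
    terms: pd.DataFrame  # term, beta, se, ci_low, ci_high, p (+ OR columns)
    fit: dict[str, float]
    n_obs: int
    flagged: bool = False  # separation / non-convergence


def _build_design(
    features: pd.DataFrame, terms: list[str], scales: dict[str, float] | None
) -> tuple[pd.DataFrame, list[str]]:
    scales = scales or {}
    cols = {}
    names = []
    for t in terms:
        scale = scales.get(t, 1.0)
        name = t if scale == 1.0 else f"{t} x {scale:g}"
        col = features[t]
        if col.dtype == object or str(col.dtype) == "category":
            # binary sex coding: male = 1, female = 0
            col = (col.astype(str) == "male").astype(float)
        cols[name] = col.astype(float) * scale
        names.append(name)
    return pd.DataFrame(cols, index=features.index), names


def linear_model_wlm(
    features: pd.DataFrame,
    terms: list[str],
    dependent: str = "wlm",
    scales: dict[str, float] | None = None,
    model_id: str = "wlm",
) -> RegressionTable:
    """Ordinary least squares of the word-list-memory score on the given
    terms (``scales`` multiplies covariates, e.g. ICV x 100)."""
    X, names = _build_design(features, terms, scales)
    frame = pd.concat([features[dependent].astype(float), X], axis=1).dropna()
    n_dropped = len(features) - len(frame)
    if n_dropped:
        logger.info("linear_model_wlm: dropped %d incomplete rows", n_dropped)
    if len(frame) < len(names) + 2:
        raise ValueError("too few complete cases for the requested terms")
    y = frame[dependent]
    X = sm.add_constant(frame[names])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design; check collinearity among {names}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": X.columns,
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    fit = {
        "r2": float(res.rsquared),
        "adj_r2": float(res.rsquared_adj),
        "f_p": float(res.f_pvalue) if res.df_model > 0 else np.nan,
    }
    return RegressionTable(model_id=model_id, terms=table, fit=fit, n_obs=int(res.nobs))


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo R^2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_cs)


def multinomial_frailty_model(
    features: pd.DataFrame,
    terms: list[str],
    group_col: str = "group",
    adjust: str = "none",
    scales: dict[str, float] | None = None,
    model_id: str = "frailty",
) -> RegressionTable:
    """Maximum-likelihood multinomial logit of frailty group (robust
    reference) on the given terms; ``adjust='age_sex'`` prepends age and sex.

    Per-term output: beta, SE, OR = exp(beta), Wald 95% CI (OR scale) and p,
    for each of the two non-reference outcomes.  Whole-model fit: likelihood
    ratio against intercept-only, Nagelkerke R^2, AIC.  Separation
    (divergent |beta|) flags the model and blanks the estimates.
    """
    if adjust not in ("none", "age_sex"):
        raise ValueError("adjust must be 'none' or 'age_sex'")
    all_terms = (["age", "sex"] if adjust == "age_sex" else []) + [
        t for t in terms if not (adjust == "age_sex" and t in ("age", "sex"))
    ]
    X, names = _build_design(features, all_terms, scales)
    grp = features[group_col].astype(str)
    frame = pd.concat([grp.rename("__group"), X], axis=1).dropna()
    frame = frame[frame["__group"].isin(GROUP_ORDER)]
    n_dropped = len(features) - len(frame)
    if n_dropped:
        logger.info("multinomial model: dropped %d incomplete rows", n_dropped)
    present = set(frame["__group"])
    if present != set(GROUP_ORDER):
        raise ValueError(f"all three groups must be represented, got {sorted(present)}")
    codes = frame["__group"].map({g: i for i, g in enumerate(GROUP_ORDER)}).to_numpy()
    n = len(frame)
    design = sm.add_constant(frame[names])
    model = sm.MNLogit(codes, design)
    res = model.fit(method="newton", maxiter=200, disp=False)
    null = sm.MNLogit(codes, np.ones((n, 1))).fit(method="newton", maxiter=200, disp=False)

    k_params = res.params.size
    lr = 2.0 * (res.llf - null.llf)
    lr_df = k_params - null.params.size
    fit = {
        "ll": float(res.llf),
        "ll_null": float(null.llf),
        "lr_p": float(stats.chi2.sf(lr, lr_df)),
        "nagelkerke_r2": _nagelkerke(res.llf, null.llf, n),
        "aic": float(res.aic),
    }
    params = np.asarray(res.params)       # (k, 2) columns: prefrail, frail
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    flagged = (
        bool(np.isnan(params).any())
        or bool(np.nanmax(np.abs(params)) > _SEPARATION_BETA)
        or not res.mle_retvals.get("converged", True)
    )
    rows = []
    term_names = list(design.columns)
    for col, outcome in enumerate(["prefrail", "frail"]):
        for k, term in enumerate(term_names):
            b, se, p = params[k, col], bse[k, col], pvals[k, col]
            if flagged:
                b = se = p = np.nan
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "beta": b,
                    "se": se,
                    "or": np.exp(b),
                    "or_ci_low": np.exp(b - 1.959963984540054 * se),
                    "or_ci_high": np.exp(b + 1.959963984540054 * se),
                    "p": p,
                }
            )
    if flagged:
        logger.warning("multinomial model %s: separation or non-convergence", model_id)
    return RegressionTable(
        model_id=model_id,
        terms=pd.DataFrame(rows),
        fit=fit,
        n_obs=n,
        flagged=flagged,
    )


def build_feature_table(
    features: pd.DataFrame,
    questionnaire: pd.DataFrame,
) -> pd.DataFrame:
    """Join extracted features with questionnaire and frailty classification.

    Keeps only included participants (>= 5 valid days); logs the counts of
    exclusions and of orphan rows on either side.  Duplicate participant ids
    raise."""
    for name, df in (("features", features), ("questionnaire", questionnaire)):
        if df["participant_id"].duplicated().any():
            raise ValueError(f"duplicate participant ids in {name}")
    if features.empty:
        logger.warning("build_feature_table: empty feature store")
        return pd.DataFrame()
    cls = classify_frailty_table(questionnaire)
    q = questionnaire.merge(cls, on="participant_id")
    merged = features.merge(q, on="participant_id", how="inner")
    orphans = len(features) + len(questionnaire) - 2 * len(merged)
    if orphans:
        logger.info("build_feature_table: %d unmatched rows dropped", orphans)
    if "included" in merged.columns:
        n_excluded = int((~merged["included"].astype(bool)).sum())
        if n_excluded:
            logger.info(
                "build_feature_table: %d participants excluded by the "
                "valid-day rule (%d retained)",
                n_excluded, len(merged) - n_excluded,
            )
        merged = merged[merged["included"].astype(bool)]
    merged["group"] = pd.Categorical(merged["group"], categories=GROUP_ORDER)
    return merged.reset_index(drop=True)
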