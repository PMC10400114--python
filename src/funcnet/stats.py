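"""Group-level statistics for connectome metrics and mTBI covariates.

The analysis plan mirrors a conventional clinical-neuroimaging report:
outcome variables are gated on a Shapiro-Wilk normality test (alpha 0.05);
normally distributed metrics get parametric comparisons (pooled two-sample
t, one-way ANOVA), non-normal ones get rank-based equivalents (Wilcoxon
rank sum with tie-corrected normal approximation, Kruskal-Wallis).
Lifetime injury incidence is binned ordinally (0, 1-2, 3+), and continuous
incidence is related to assortativity by ordinary least squares with age
controlled via backwards elimination.  All tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "TestResult",
    "RegressionResult",
    "normality_gate",
    "two_sample_ttest",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "one_way_anova",
    "bin_incidence",
    "ols_backwards_elimination",
    "summarize_demographics",
    "format_table1",
    "run_analysis_plan",
    "RECENCY_CATEGORIES",
    "INCIDENCE_BINS",
]

DEFAULT_ALPHA = 0.05
DEFAULT_ALPHA_REMOVE = 0.05
RECENCY_CATEGORIES = ("past_month", "past_year", "year_plus", "not_reported")
INCIDENCE_BINS = ("0", "1-2", "3+")


@dataclass
class NormalityResult:
    classification: str  # "normal" | "non_normal"
    statistic: float | None
    p_value: float | None
    degenerate: bool
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray

    @property
    def normal(self) -> bool:
        return self.classification == "normal"


@dataclass
class TestResult:
    name: str
    statistic_symbol: str  # t | z | chi_square | F
    statistic: float
    df: tuple[float, ...]
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic_symbol": self.statistic_symbol,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
        }


@dataclass
class RegressionResult:
    slope: float  # unstandardized B for the predictor
    intercept: float
    f_statistic: float
    df: tuple[float, float]
    r_squared: float
    beta_standardized: float
    retained_covariates: list[str]
    n_used: int
    predictor_p: float

    def as_dict(self) -> dict:
        return {
            "B": self.slope,
            "intercept": self.intercept,
            "F": self.f_statistic,
            "df": list(self.df),
            "r_squared": self.r_squared,
            "beta": self.beta_standardized,
            "retained_covariates": self.retained_covariates,
            "n": self.n_used,
            "predictor_p": self.predictor_p,
        }


def normality_gate(values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> NormalityResult:
    """Shapiro-Wilk normality classification with Q-Q plot coordinates.

    The gate is the Shapiro-Wilk p-value alone; the Q-Q coordinates
    (theoretical normal vs sample quantiles) are emitted for optional visual
    inspection and never gate automatically.  A constant vector is classed
    non-normal with a degenerate flag.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("normality test needs at least 3 finite values")
    (osm, osr), _ = sps.probplot(x, dist="norm", fit=True)
    if np.ptp(x) == 0.0:
        return NormalityResult("non_normal", None, None, True, osm, osr)
    w, p = sps.shapiro(x)
    cls = "normal" if p > alpha else "non_normal"
    return NormalityResult(cls, float(w), float(p), False, osm, osr)


def _summaries(groups: dict[str, np.ndarray]) -> dict:
    out = {}
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        out[name] = {
            "n": int(g.size),
            "mean": float(g.mean()),
            "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0,
            "median": float(np.median(g)),
        }
    return out


def two_sample_ttest(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided independent two-sample t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        name="two_sample_ttest",
        statistic_symbol="t",
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        group_summaries=_summaries({"a": a, "b": b}),
    )


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Wilcoxon rank sum with midranks, tie-corrected variance and continuity.

    Reports the normal-approximation z for the rank sum of the first group
    and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        raise ValueError("all values identical: no ordering information")
    n1, n2 = a.size, b.size
    N = n1 + n2
    ranks = sps.rankdata(pooled)  # midranks
    W = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        raise ValueError("degenerate rank variance")
    delta = W - mu
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    res = TestResult(
        name="wilcoxon_rank_sum",
        statistic_symbol="z",
        statistic=float(z),
        df=(1.0,),
        p_value=float(min(p, 1.0)),
        group_summaries=_summaries({"a": a, "b": b}),
    )
    res.group_summaries["rank_sum_a"] = float(W)
    return res


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square reference."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 1 for g in arrays):
        raise ValueError("every group needs at least 1 observation")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(np.concatenate(arrays)) == 0.0:
        raise ValueError("all values identical: rank statistic undefined")
    h, p = sps.kruskal(*arrays)
    return TestResult(
        name="kruskal_wallis",
        statistic_symbol="chi_square",
        statistic=float(h),
        df=(float(len(arrays) - 1),),
        p_value=float(p),
        group_summaries=_summaries({str(i): g for i, g in enumerate(arrays)}),
    )


def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """One-way fixed-effects ANOVA (the parametric counterpart of KW)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0.0:
        raise ValueError("all values identical: F statistic undefined")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    return TestResult(
        name="one_way_anova",
        statistic_symbol="F",
        statistic=float(f),
        df=(float(k - 1), float(n - k)),
        p_value=float(p),
        group_summaries=_summaries({str(i): g for i, g in enumerate(arrays)}),
    )


def bin_incidence(count) -> str | None:
    """Ordinal lifetime-incidence bin: 0, 1-2, 3+; missing -> None."""
    if count is None or (isinstance(count, float) and math.isnan(count)):
        return None
    c = float(count)
    if c < 0:
        raise ValueError("incidence count cannot be negative")
    if c == 0:
        return "0"
    if c <= 2:
        return "1-2"
    return "3+"


def ols_backwards_elimination(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
    alpha_remove: float = DEFAULT_ALPHA_REMOVE,
) -> RegressionResult:
    """OLS of outcome on predictor, covariates pruned by backwards elimination.

    The covariate with the largest p-value above ``alpha_remove`` is removed
    and the model refit until every remaining covariate is significant; the
    predictor itself is never removed.  The standardized coefficient is
    ``beta = B * sd(predictor) / sd(outcome)``; for a final single-predictor
    model ``|beta| = sqrt(R^2)`` holds as an algebraic identity.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    covariates = dict(covariates or {})
    cols = {"predictor": x, **{k: np.asarray(v, dtype=float) for k, v in covariates.items()}}
    X = pd.DataFrame(cols)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[mask], X.loc[mask]
    if y.size <= X.shape[1] + 1:
        raise ValueError("more parameters than observations")
    current = list(X.columns)
    while True:
        design = sm.add_constant(X[current])
        cond = np.linalg.cond(design.to_numpy())
        if cond > 1e10:
            raise ValueError(f"collinear design (condition number {cond:.3g}): {current}")
        fit = sm.OLS(y, design).fit()
        cov_ps = {c: fit.pvalues[c] for c in current if c != "predictor"}
        if not cov_ps:
            break
        worst = max(cov_ps, key=cov_ps.get)
        if cov_ps[worst] > alpha_remove:
            current.remove(worst)
        else:
            break
    B = float(fit.params["predictor"])
    beta = B * float(np.std(X.loc[:, "predictor"], ddof=1)) / float(np.std(y, ddof=1))
    return RegressionResult(
        slope=B,
        intercept=float(fit.params["const"]),
        f_statistic=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        r_squared=float(fit.rsquared),
        beta_standardized=beta,
        retained_covariates=[c for c in current if c != "predictor"],
        n_used=int(y.size),
        predictor_p=float(fit.pvalues["predictor"]),
    )


def _pct(k: int, n: int) -> float:
    """Column percentage, two decimals, half away from zero."""
    if n == 0:
        return 0.0
    q = (Decimal(100) * Decimal(k) / Decimal(n)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def summarize_demographics(cohort: pd.DataFrame) -> dict:
    """Demographic summary by mTBI-history column and in total.

    Frequencies with column percentages (two decimals, relative to column
    total frequency), mean (SD) age, median (IQR) lifetime count, ordinal
    incidence bins and recency bins.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    df = cohort.copy()
    hist = df["mtbi_history"].astype(bool)
    columns = {
        "no_history": df[~hist],
        "history": df[hist],
        "total": df,
    }
    n_total = len(df)
    out: dict = {"frequency": {}, "age": {}, "median_count": {}, "incidence": {}, "recency": {}}
    for name, sub in columns.items():
        n = len(sub)
        out["frequency"][name] = {"n": n, "pct": _pct(n, n_total)}
        if n:
            ages = sub["age"].to_numpy(dtype=float)
            out["age"][name] = {"mean": float(ages.mean()), "sd": float(ages.std(ddof=1)) if n > 1 else 0.0}
        counts = sub.loc[sub["mtbi_history"].astype(bool), "mtbi_count"].dropna()
        if len(counts):
            q75, q25 = np.percentile(counts, [75, 25])
            out["median_count"][name] = {"median": float(np.median(counts)), "iqr": float(q75 - q25)}
        bins = {b: 0 for b in INCIDENCE_BINS}
        missing = 0
        for c in sub["mtbi_count"]:
            b = bin_incidence(c)
            if b is None:
                missing += 1
            else:
                bins[b] += 1
        inc = {b: {"n": k, "pct": _pct(k, n)} for b, k in bins.items()}
        inc["not_reported"] = {"n": missing, "pct": _pct(missing, n)}
        out["incidence"][name] = inc
        rec = {}
        if "mtbi_recency" in sub.columns:
            values = sub.loc[sub["mtbi_history"].astype(bool), "mtbi_recency"].fillna("not_reported")
            for cat in RECENCY_CATEGORIES:
                k = int((values == cat).sum())
                rec[cat] = {"n": k, "pct": _pct(k, n)}
        out["recency"][name] = rec
    return out


def format_table1(summary: dict) -> str:
    """Human-readable rendering of the demographic summary."""
    lines = ["Variable\tNo history\tHistory\tTotal"]
    cols = ("no_history", "history", "total")

    def cell(d):
        return f"{d['n']} ({d['pct']:.2f}%)" if d else ""

    lines.append("Frequency (%)\t" + "\t".join(cell(summary["frequency"][c]) for c in cols))
    lines.append(
        "Mean age (SD), years\t"
        + "\t".join(
            f"{summary['age'][c]['mean']:.1f} ({summary['age'][c]['sd']:.1f})"
            if c in summary["age"]
            else ""
            for c in cols
        )
    )
    lines.append(
        "Median count (IQR)\t"
        + "\t".join(
            f"{summary['median_count'][c]['median']:.0f} ({summary['median_count'][c]['iqr']:.0f})"
            if c in summary["median_count"]
            else ""
            for c in cols
        )
    )
    lines.append("Lifetime incidence")
    for b in (*INCIDENCE_BINS, "not_reported"):
        lines.append(f"  {b}\t" + "\t".join(cell(summary["incidence"][c].get(b)) for c in cols))
    lines.append("Recency")
    for cat in RECENCY_CATEGORIES:
        lines.append(f"  {cat}\t" + "\t".join(cell(summary["recency"][c].get(cat)) for c in cols))
    return "\n".join(lines)


_METRICS = ("ge", "le", "ac")


def run_analysis_plan(
    cohort: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    alpha_remove: float = DEFAULT_ALPHA_REMOVE,
) -> dict:
    """Full group-level analysis over a cohort table with computed metrics.

    For each metric (ge, le, ac): Shapiro-Wilk gate; binary-history
    comparison by pooled t (normal) or Wilcoxon rank sum (non-normal);
    comparison over ordinal incidence bins and over recency categories by
    one-way ANOVA (normal) or Kruskal-Wallis (non-normal).  Continuous
    lifetime incidence is regressed on assortativity with age controlled by
    backwards elimination; subjects without a continuous count are excluded
    from the regression (listwise).  Degenerate-variance failures are
    recorded as structured error entries, never silent zeros.
    """
    df = cohort.copy()
    report: dict = {"n": int(len(df)), "alpha": alpha, "metrics": {}, "regression": {}}
    for m in _METRICS:
        vals = df[m].to_numpy(dtype=float)
        frac_undefined = np.mean(~np.isfinite(vals))
        if frac_undefined > 0.20:
            raise ValueError(
                f"metric {m!r} undefined for {frac_undefined:.0%} of subjects (> 20%)"
            )
    hist = df["mtbi_history"].astype(bool)

    def _safe(fn, *args):
        try:
            res = fn(*args)
            return res.as_dict()
        except ValueError as exc:
            return {"error": str(exc)}

    for m in _METRICS:
        entry: dict = {}
        valid = df[np.isfinite(df[m].to_numpy(dtype=float))]
        vals = valid[m].to_numpy(dtype=float)
        gate = normality_gate(vals, alpha=alpha)
        entry["normality"] = {
            "classification": gate.classification,
            "p_value": gate.p_value,
            "degenerate": gate.degenerate,
        }
        vh = valid["mtbi_history"].astype(bool)
        a = valid.loc[vh, m].to_numpy(dtype=float)
        b = valid.loc[~vh, m].to_numpy(dtype=float)
        entry["history"] = _safe(two_sample_ttest if gate.normal else wilcoxon_rank_sum, a, b)

        bins = valid["mtbi_count"].map(bin_incidence)
        inc_groups = [
            valid.loc[bins == lab, m].to_numpy(dtype=float) for lab in INCIDENCE_BINS
        ]
        inc_groups = [g for g in inc_groups if g.size > 0]
        if len(inc_groups) >= 2:
            entry["incidence"] = _safe(
                one_way_anova if gate.normal else kruskal_wallis, inc_groups
            )
        else:
            entry["incidence"] = {"error": "fewer than 2 incidence bins populated"}

        rec = valid.loc[vh & valid["mtbi_recency"].isin(RECENCY_CATEGORIES[:3])]
        rec_groups = [
            rec.loc[rec["mtbi_recency"] == cat, m].to_numpy(dtype=float)
            for cat in RECENCY_CATEGORIES[:3]
        ]
        rec_groups = [g for g in rec_groups if g.size > 0]
        if len(rec_groups) >= 2:
            entry["recency"] = _safe(
                one_way_anova if gate.normal else kruskal_wallis, rec_groups
            )
        else:
            entry["recency"] = {"error": "fewer than 2 recency groups populated"}
        report["metrics"][m] = entry

    reg_df = df[np.isfinite(df["ac"].to_numpy(dtype=float)) & df["mtbi_count"].notna()]
    report["regression"]["n_excluded_missing_count"] = int(len(df) - len(reg_df))
    try:
        reg = ols_backwards_elimination(
            reg_df["ac"].to_numpy(dtype=float),
            reg_df["mtbi_count"].to_numpy(dtype=float),
            {"age": reg_df["age"].to_numpy(dtype=float)},
            alpha_remove=alpha_remove,
        )
        report["regression"]["ac_incidence"] = reg.as_dict()
    except ValueError as exc:
        report["regression"]["ac_incidence"] = {"error": str(exc)}
    return report
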