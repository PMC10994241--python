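"""Cohort-level outcome analysis.

Mirrors a standard retrospective precision-oncology analysis: Kaplan-Meier
curves and log-rank tests per dichotomous covariate, univariate and
multivariate Cox proportional-hazards models for PFS/OS, Fisher exact
tests and logistic regression for clinical benefit, a P < 0.1 univariate
screen for multivariate entry, and ROC/Youden selection of the score
cutoff used to dichotomise patients.

Kaplan-Meier, log-rank and Cox fits stand on lifelines; logistic models
on statsmodels; Fisher's exact p on scipy.  The surrounding contracts
(medians, Woolf confidence intervals, screening, report assembly) are
implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CovariateEffect",
    "ContingencyResult",
    "CohortReport",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "contingency_2x2",
    "logistic_fit",
    "screen_univariate",
    "roc_cutoff",
    "analyze_cohort",
    "summarize_biomarkers",
    "round_percent",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SurvivalRecord:
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("survival time must be positive")


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival_probs: np.ndarray
    median_months: Optional[float]


@dataclass
class CovariateEffect:
    label: str
    estimate: float          # hazard ratio or odds ratio
    ci_low: float
    ci_high: float
    p_value: float
    flag: Optional[str] = None   # "separation", "no_information", ...


@dataclass
class ContingencyResult:
    rate_high: float
    rate_low: float
    odds_ratio: float
    or_ci: tuple[float, float]
    fisher_p: float
    counts: tuple[int, int, int, int]  # (benefit_high, n_high, benefit_low, n_low)


def round_percent(proportion: float) -> int:
    """Integer percent, rounded half-up (0.714 -> 71)."""
    return int(
        Decimal(proportion * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([r.time_months for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=bool)
    return t, e


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate with its median.

    Median is the smallest time at which survival drops to <= 0.5;
    ``None`` when the curve never reaches 0.5.
    """
    if not records:
        raise ValueError("at least one survival record is required")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    probs = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(event_times=times, survival_probs=probs, median_months=median)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square, two-sided p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("a group has zero observed events; log-rank has little power")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame | np.ndarray,
    ties: str = "efron",
) -> list[CovariateEffect]:
    """Cox proportional-hazards fit; one effect per covariate column.

    Efron tie handling by default (Breslow available).  Constant
    covariates are reported as HR 1, p 1 with a ``no_information`` flag;
    monotone likelihoods (perfect separation) are flagged with an
    unbounded confidence interval.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _to_arrays(records)
    if e.sum() == 0:
        raise ValueError("Cox regression requires at least one event")
    X = pd.DataFrame(covariates).copy()
    X.columns = [str(c) for c in X.columns]
    labels = list(X.columns)

    constant = [c for c in labels if X[c].nunique() <= 1]
    informative = [c for c in labels if c not in constant]
    fitted: dict[str, CovariateEffect] = {}
    for c in constant:
        fitted[c] = CovariateEffect(c, 1.0, float("nan"), float("nan"), 1.0,
                                    flag="no_information")

    if informative:
        try:
            if ties == "efron":
                betas, ses, ps = _cox_efron_lifelines(t, e, X[informative])
            else:
                betas, ses, ps = _cox_breslow_newton(
                    t, e, X[informative].to_numpy(dtype=float))
        except Exception as exc:  # monotone likelihood / convergence failure
            for c in informative:
                fitted[c] = CovariateEffect(
                    c, float("nan"), 0.0, float("inf"), float("nan"),
                    flag=f"convergence_failure: {exc}",
                )
            informative = []
        for j, c in enumerate(informative):
            beta, se, p = betas[j], ses[j], ps[j]
            unstable = abs(beta) > 15 or not np.isfinite(se)
            fitted[c] = CovariateEffect(
                label=c,
                estimate=math.exp(beta),
                ci_low=0.0 if unstable else math.exp(beta - Z95 * se),
                ci_high=float("inf") if unstable else math.exp(beta + Z95 * se),
                p_value=float(p),
                flag="separation" if unstable else None,
            )
    return [fitted[c] for c in labels]


def _cox_efron_lifelines(t, e, X: pd.DataFrame):
    df = X.copy()
    df["time"], df["event"] = t, e.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    betas = [float(cph.params_[c]) for c in X.columns]
    ses = [float(cph.standard_errors_[c]) for c in X.columns]
    ps = [float(cph.summary.loc[c, "p"]) for c in X.columns]
    return betas, ses, ps


def _cox_breslow_newton(t, e, X, max_iter=100, tol=1e-9):
    """Newton-Raphson maximiser of the Breslow partial likelihood.

    Ties share one risk-set denominator per event time.  Returns
    (betas, Wald SEs, two-sided p) per column.
    """
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], np.asarray(X, dtype=float)[order]
    n, p = X.shape
    beta = np.zeros(p)
    event_times = np.unique(t[e])
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(eta - eta.max())
        U = np.zeros(p)
        H = np.zeros((p, p))
        for tau in event_times:
            risk = t >= tau
            dead = (t == tau) & e
            wr = w[risk]
            s0 = wr.sum()
            s1 = wr @ X[risk]
            xbar = s1 / s0
            s2 = (X[risk] * wr[:, None]).T @ X[risk]
            d = int(dead.sum())
            U += X[dead].sum(axis=0) - d * xbar
            H += d * (s2 / s0 - np.outer(xbar, xbar))
        step = np.linalg.solve(H, U)
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            raise RuntimeError("Breslow Cox fit diverged (monotone likelihood?)")
        if np.abs(step).max() < tol:
            break
    else:
        raise RuntimeError("Breslow Cox fit did not converge")
    cov = np.linalg.inv(H)
    ses = np.sqrt(np.diag(cov))
    z = beta / ses
    ps = 2 * stats.norm.sf(np.abs(z))
    return list(beta), list(ses), list(ps)


def contingency_2x2(
    benefit_high: int, n_high: int, benefit_low: int, n_low: int
) -> ContingencyResult:
    """Benefit rates, odds ratio with Woolf 95% CI, and Fisher exact p.

    The Haldane-Anscombe 0.5 correction is applied to the OR and CI when
    any cell is zero; the Fisher p always uses the uncorrected table.
    """
    if n_high <= 0 or n_low <= 0:
        raise ValueError("each group must contain at least one patient")
    if not (0 <= benefit_high <= n_high and 0 <= benefit_low <= n_low):
        raise ValueError("benefit counts must lie within group sizes")
    a, b = benefit_high, n_high - benefit_high
    c, d = benefit_low, n_low - benefit_low
    cells = [a, b, c, d]
    if 0 in cells:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    odds_ratio = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci = (odds_ratio * math.exp(-Z95 * se), odds_ratio * math.exp(Z95 * se))
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(
        rate_high=benefit_high / n_high,
        rate_low=benefit_low / n_low,
        odds_ratio=odds_ratio,
        or_ci=ci,
        fisher_p=float(fisher_p),
        counts=(benefit_high, n_high, benefit_low, n_low),
    )


def logistic_fit(
    outcome: Sequence[bool] | np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
) -> list[CovariateEffect]:
    """Maximum-likelihood logistic regression; odds ratios with Wald CIs.

    Complete or quasi-complete separation is detected and flagged with an
    unbounded CI instead of a spurious finite estimate.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = pd.DataFrame(covariates).copy()
    X.columns = [str(c) for c in X.columns]
    labels = list(X.columns)
    Xc = sm.add_constant(X.astype(float), has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            # singular Hessian: complete or quasi-complete separation
            return [
                CovariateEffect(c, float("nan"), 0.0, float("inf"),
                                float("nan"), flag="separation")
                for c in labels
            ]
    effects = []
    for c in labels:
        beta = float(fit.params[c])
        se = float(fit.bse[c])
        flagged = abs(beta) > 15 or not np.isfinite(se) or se > 50
        effects.append(
            CovariateEffect(
                label=c,
                estimate=math.exp(beta),
                ci_low=0.0 if flagged else math.exp(beta - Z95 * se),
                ci_high=float("inf") if flagged else math.exp(beta + Z95 * se),
                p_value=float("nan") if flagged else float(fit.pvalues[c]),
                flag="separation" if flagged else None,
            )
        )
    return effects


def screen_univariate(
    comparisons: Iterable[tuple[str, float]], alpha_enter: float = 0.1
) -> list[str]:
    """Labels whose univariate p-value is strictly below ``alpha_enter``.

    Input order is preserved.  Callers skip the multivariate step when
    fewer than two labels are selected.
    """
    return [label for label, p in comparisons if p < alpha_enter]


def roc_cutoff(
    scores: Sequence[float],
    benefit_labels: Sequence[bool],
    candidate_cutoffs: Optional[Sequence[float]] = None,
    criterion: str = "youden",
) -> float:
    """Score cutoff maximising the Youden index for clinical benefit.

    Patients are called positive when score > cutoff (strict).  Ties are
    broken toward the larger cutoff.  ``criterion="benefit_diff"``
    maximises the benefit-rate difference between the two groups instead.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(benefit_labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one benefiting and one non-benefiting patient")
    if criterion not in ("youden", "benefit_diff"):
        raise ValueError("criterion must be 'youden' or 'benefit_diff'")
    candidates = (
        np.unique(scores) if candidate_cutoffs is None
        else np.unique(np.asarray(candidate_cutoffs, dtype=float))
    )
    best_c, best_val = None, -np.inf
    for c in candidates:
        pred = scores > c
        if criterion == "youden":
            sens = (pred & labels).sum() / n_pos
            spec = (~pred & ~labels).sum() / n_neg
            val = sens + spec - 1
        else:
            if pred.sum() == 0 or (~pred).sum() == 0:
                continue
            val = labels[pred].mean() - labels[~pred].mean()
        if val >= best_val:  # >= breaks ties toward the larger cutoff
            best_c, best_val = float(c), val
    return best_c


# ---------------------------------------------------------------------------
# Table-style cohort report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Structured univariate + multivariate outcome analysis."""

    pfs: dict = field(default_factory=dict)
    os: dict = field(default_factory=dict)
    benefit: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pfs": self.pfs,
            "os": self.os,
            "benefit": self.benefit,
            "warnings": self.warnings,
        }

    def to_markdown(self) -> str:
        lines = []
        for endpoint in ("pfs", "os"):
            section = getattr(self, endpoint)
            lines.append(f"## {endpoint.upper()}")
            lines.append("| Covariate | Median (1 vs 0), months | Log-rank P "
                         "| HR (95% CI) | Multivariate HR (95% CI) | P |")
            lines.append("|---|---|---|---|---|---|")
            multi = section.get("multivariate") or {}
            for cov, row in section.get("univariate", {}).items():
                m1 = _fmt_num(row["median_1"])
                m0 = _fmt_num(row["median_0"])
                hr = f"{row['hr']:.2f} ({row['hr_ci'][0]:.2f}-{row['hr_ci'][1]:.2f})"
                if cov in multi:
                    mrow = multi[cov]
                    mtxt = (f"{mrow['hr']:.2f} "
                            f"({mrow['hr_ci'][0]:.2f}-{mrow['hr_ci'][1]:.2f})")
                    mp = f"{mrow['p']:.3f}"
                else:
                    mtxt = mp = "—"
                lines.append(
                    f"| {cov} | {m1} vs {m0} | {row['logrank_p']:.3f} "
                    f"| {hr} | {mtxt} | {mp} |"
                )
            lines.append("")
        lines.append("## Clinical benefit")
        lines.append("| Covariate | Rate (N) | Fisher P | OR (95% CI) "
                     "| Multivariate OR (95% CI) | P |")
        lines.append("|---|---|---|---|---|---|")
        multi = self.benefit.get("multivariate") or {}
        for cov, row in self.benefit.get("univariate", {}).items():
            bh, nh, bl, nl = row["counts"]
            rate = (f"{round_percent(row['rate_1'])}% ({bh}/{nh}) vs. "
                    f"{round_percent(row['rate_0'])}% ({bl}/{nl})")
            or_ = (f"{row['or']:.2f} "
                   f"({row['or_ci'][0]:.2f}-{row['or_ci'][1]:.2f})")
            if cov in multi:
                mrow = multi[cov]
                mtxt = (f"{mrow['or']:.2f} "
                        f"({mrow['or_ci'][0]:.2f}-{mrow['or_ci'][1]:.2f})")
                mp = f"{mrow['p']:.3f}"
            else:
                mtxt = mp = "—"
            lines.append(f"| {cov} | {rate} | {row['fisher_p']:.3f} "
                         f"| {or_} | {mtxt} | {mp} |")
        lines.append("")
        return "\n".join(lines)


def _fmt_num(x) -> str:
    return "NR" if x is None else f"{x:.1f}"


def _survival_records(df: pd.DataFrame, time_col: str, event_col: str):
    return [
        SurvivalRecord(t, bool(e))
        for t, e in zip(df[time_col], df[event_col])
        if np.isfinite(t)
    ]


def analyze_cohort(
    df: pd.DataFrame,
    covariates: Sequence[str],
    cutoff: float = 50.0,
    alpha_enter: float = 0.1,
    ties: str = "efron",
) -> CohortReport:
    """Full outcome analysis over binary covariates.

    ``df`` needs columns ``pfs_months, pfs_event, os_months, os_event``
    and (optionally) a boolean ``benefit`` column; each name in
    ``covariates`` must be a 0/1 or boolean column.  The report carries,
    per endpoint: per-covariate KM medians, log-rank p, univariate Cox
    HR, the P < ``alpha_enter`` screen, and a multivariate Cox (PFS/OS)
    or logistic (benefit) model when two or more covariates pass.
    """
    if df.empty:
        raise ValueError("cohort is empty")
    report = CohortReport()
    usable: list[str] = []
    for cov in covariates:
        vals = df[cov].astype(float)
        if vals.nunique() < 2 or vals.value_counts().min() < 2:
            report.warnings.append(
                f"covariate {cov!r} skipped: fewer than 2 patients per level"
            )
            continue
        usable.append(cov)

    for endpoint, (time_col, event_col) in {
        "pfs": ("pfs_months", "pfs_event"),
        "os": ("os_months", "os_event"),
    }.items():
        sub = df[np.isfinite(df[time_col].astype(float))]
        uni: dict[str, dict] = {}
        for cov in usable:
            mask = sub[cov].astype(bool)
            g1 = _survival_records(sub[mask], time_col, event_col)
            g0 = _survival_records(sub[~mask], time_col, event_col)
            if not g1 or not g0:
                report.warnings.append(
                    f"{endpoint}: covariate {cov!r} skipped, empty level"
                )
                continue
            chi2, p = logrank_test(g1, g0)
            effect = cox_fit(g1 + g0,
                             pd.DataFrame({cov: [1] * len(g1) + [0] * len(g0)}),
                             ties=ties)[0]
            uni[cov] = {
                "median_1": km_curve(g1).median_months,
                "median_0": km_curve(g0).median_months,
                "logrank_p": p,
                "logrank_chi2": chi2,
                "hr": effect.estimate,
                "hr_ci": (effect.ci_low, effect.ci_high),
                "hr_p": effect.p_value,
            }
        selected = screen_univariate(
            [(cov, row["logrank_p"]) for cov, row in uni.items()], alpha_enter
        )
        multivariate = None
        if len(selected) >= 2:
            records = _survival_records(sub, time_col, event_col)
            effects = cox_fit(records, sub[selected].astype(float), ties=ties)
            multivariate = {
                e.label: {"hr": e.estimate, "hr_ci": (e.ci_low, e.ci_high),
                          "p": e.p_value, "flag": e.flag}
                for e in effects
            }
        getattr(report, endpoint).update(
            univariate=uni, selected=selected, multivariate=multivariate
        )

    if "benefit" in df.columns:
        bsub = df[df["benefit"].notna()].copy()
        bsub["benefit"] = bsub["benefit"].astype(bool)
        uni = {}
        for cov in usable:
            mask = bsub[cov].astype(bool)
            n1, n0 = int(mask.sum()), int((~mask).sum())
            if n1 == 0 or n0 == 0:
                continue
            res = contingency_2x2(
                int(bsub.loc[mask, "benefit"].sum()), n1,
                int(bsub.loc[~mask, "benefit"].sum()), n0,
            )
            uni[cov] = {
                "rate_1": res.rate_high,
                "rate_0": res.rate_low,
                "counts": res.counts,
                "fisher_p": res.fisher_p,
                "or": res.odds_ratio,
                "or_ci": res.or_ci,
            }
        selected = screen_univariate(
            [(cov, row["fisher_p"]) for cov, row in uni.items()], alpha_enter
        )
        multivariate = None
        if len(selected) >= 2:
            effects = logistic_fit(
                bsub["benefit"].to_numpy(), bsub[selected].astype(float)
            )
            multivariate = {
                e.label: {"or": e.estimate, "or_ci": (e.ci_low, e.ci_high),
                          "p": e.p_value, "flag": e.flag}
                for e in effects
            }
        report.benefit.update(
            univariate=uni, selected=selected, multivariate=multivariate
        )
    return report


def summarize_biomarkers(profiles: Iterable) -> dict:
    """Descriptive immune-biomarker summary over a cohort.

    Rates are computed over patients tested for each marker: MSI-high
    fraction, TMB category proportions, TMB >= 10 mut/Mb fraction, and
    PD-L1 positivity (>= 1%).
    """
    from .patient_model import MSIStatus, classify_tmb

    msi_tested = msi_high = 0
    tmb_tested = tmb_ge10 = 0
    tmb_cats = {"low": 0, "intermediate": 0, "high": 0}
    pdl1_tested = pdl1_pos = 0
    for p in profiles:
        bm = p.biomarkers
        if bm.msi_status is not MSIStatus.UNKNOWN:
            msi_tested += 1
            msi_high += bm.msi_status is MSIStatus.MSI_HIGH
        if bm.tmb_mut_per_mb is not None:
            tmb_tested += 1
            tmb_ge10 += bm.tmb_mut_per_mb >= 10
            tmb_cats[classify_tmb(bm.tmb_mut_per_mb).value] += 1
        if bm.pdl1_percent is not None:
            pdl1_tested += 1
            pdl1_pos += bm.pdl1_percent >= 1
    return {
        "msi_tested": msi_tested,
        "msi_high": msi_high,
        "msi_high_rate": msi_high / msi_tested if msi_tested else float("nan"),
        "tmb_tested": tmb_tested,
        "tmb_ge10": tmb_ge10,
        "tmb_ge10_rate": tmb_ge10 / tmb_tested if tmb_tested else float("nan"),
        "tmb_category_counts": tmb_cats,
        "pdl1_tested": pdl1_tested,
        "pdl1_positive": pdl1_pos,
        "pdl1_positive_rate": pdl1_pos / pdl1_tested if pdl1_tested else float("nan"),
    }
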