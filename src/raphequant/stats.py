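"""Statistical layer: heteroscedastic t-tests, ANOVA, Box-Cox, FDR.

The workflow mirrors common practice for grouped anatomy/physiology data:
groups meeting the equal-variance assumption go to t-tests or one-/two-way
ANOVA; a Spearman rank test of |residuals| against fitted values gatekeeps
that assumption; failing data are Box-Cox transformed (MLE lambda) and
re-tested; data failing even then are compared with summary-based Welch
t-tests.  Families of comparisons are Benjamini-Hochberg adjusted at FDR
0.05.  Significance stars follow 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "BoxCoxFit",
    "welch_t_from_summaries",
    "paired_t",
    "oneway_anova",
    "tukey_hsd",
    "twoway_anova",
    "boxcox",
    "boxcox_transform",
    "spearman_hetero_test",
    "benjamini_hochberg",
    "adjust_family",
]

STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")

    @property
    def stars(self) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return "".join("*" for lvl in STAR_LEVELS if p < lvl)


@dataclass
class BoxCoxFit:
    lmbda: float
    loglik: float
    transformed: np.ndarray


def welch_t_from_summaries(m1: float, sem1: float, n1: int,
                           m2: float, sem2: float, n2: int,
                           name: str = "welch") -> TestResult:
    """Welch (heteroscedastic) t-test directly from group summaries.

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2); the Welch-Satterthwaite df uses
    the squared-SEM terms: df = (sem1^2 + sem2^2)^2 /
    (sem1^4/(n1-1) + sem2^4/(n2-1)).  Identical to a raw-data Welch test when
    the summaries are computed from the samples.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be >= 0")
    v = sem1**2 + sem2**2
    if v == 0:
        if m1 == m2:
            raise ValueError("t undefined: both SEMs zero with equal means")
        raise ValueError("t undefined: both SEMs zero")
    t = (m1 - m2) / np.sqrt(v)
    df = v**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(name=name, statistic=float(t), df=float(df), p=float(p))


def paired_t(x, y, name: str = "paired t") -> TestResult:
    """Paired t-test on per-unit differences; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t needs at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(name=name, statistic=float(t), df=float(n - 1), p=float(p))


def oneway_anova(groups: list[np.ndarray], name: str = "one-way ANOVA") -> TestResult:
    """Classical between/within decomposition; F with (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    if df_w <= 0:
        raise ValueError("not enough observations for a within-group df")
    ms_w = ss_within / df_w
    if ss_between <= 1e-12 * max(ss_within, 1.0):
        f, p = 0.0, 1.0
    elif ms_w == 0:
        f, p = np.inf, 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = sps.f.sf(f, df_b, df_w)
    return TestResult(name=name, statistic=float(f), df=(float(df_b), float(df_w)),
                      p=float(p))


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None
              ) -> list[TestResult]:
    """Pairwise Tukey HSD comparisons (studentized-range adjusted p)."""
    if len(groups) < 2:
        raise ValueError("Tukey needs at least two groups")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    res = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(TestResult(
                name=f"tukey {labels[i]} vs {labels[j]}",
                statistic=float(res.statistic[i, j]),
                df=float(sum(len(g) for g in groups) - len(groups)),
                p=float(min(res.pvalue[i, j], 1.0))))
    return out


def twoway_anova(values, factor_a, factor_b, typ: int = 2,
                 name: str = "two-way ANOVA") -> dict[str, TestResult]:
    """Two-factor ANOVA with interaction; Type-II sums of squares by default.

    For balanced designs Type I/II/III coincide.  Returns TestResults keyed
    "A", "B", "A:B".  A zero effect sum of squares reports F = 0 even when
    the residual is also zero (noise-free constructions).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "A": pd.Categorical(factor_a),
                       "B": pd.Categorical(factor_b)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    fit = ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=typ)
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    resid_df = float(tab.loc["Residual", "df"])
    scale = max(float(np.var(df["y"])) * len(df), 1.0)
    out: dict[str, TestResult] = {}
    for row, key in [("C(A)", "A"), ("C(B)", "B"), ("C(A):C(B)", "A:B")]:
        ss = float(tab.loc[row, "sum_sq"])
        d1 = float(tab.loc[row, "df"])
        if ss <= 1e-12 * scale:
            f, p = 0.0, 1.0
        elif resid_ss <= 1e-12 * scale:
            f, p = np.inf, 0.0
        else:
            f = (ss / d1) / (resid_ss / resid_df)
            p = sps.f.sf(f, d1, resid_df)
        out[key] = TestResult(name=f"{name} {key}", statistic=float(f),
                              df=(d1, resid_df), p=float(p))
    return out


def _boxcox_llf(lmbda: float, x: np.ndarray) -> float:
    return float(sps.boxcox_llf(lmbda, x))


def boxcox(values, lo: float = -3.0, hi: float = 3.0) -> BoxCoxFit:
    """Box-Cox fit with MLE lambda from a grid scan + golden-section refine.

    y(lambda) = (x^lambda - 1)/lambda for lambda != 0, log x at lambda = 0.
    All inputs must be strictly positive.  Lambda is reported to 2 decimals'
    worth of precision by construction of the search (0.01 grid step, then
    local refinement).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("Box-Cox needs at least two distinct values")
    grid = np.arange(lo, hi + 1e-9, 0.01)
    llf = np.array([_boxcox_llf(l, x) for l in grid])
    k = int(np.argmax(llf))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda l: -_boxcox_llf(l, x),
                                   bracket=None, bounds=(a, b), method="bounded")
    lmbda = float(res.x)
    return BoxCoxFit(lmbda=lmbda, loglik=_boxcox_llf(lmbda, x),
                     transformed=boxcox_transform(x, lmbda))


def boxcox_transform(x, lmbda: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if lmbda == 0:
        return np.log(x)
    return (x**lmbda - 1.0) / lmbda


def spearman_hetero_test(residuals, fitted, name: str = "spearman hetero"
                         ) -> TestResult:
    """Equal-variance gatekeeper: Spearman rho of |residuals| vs fitted.

    A significant positive (or negative) rank correlation indicates that the
    spread scales with the fitted level, i.e. heteroscedasticity.  Tie-heavy
    degenerate inputs (constant |residuals| or constant fitted) report
    rho = 0, p = 1 by convention.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    f = np.asarray(fitted, dtype=float)
    if r.shape != f.shape:
        raise ValueError("residuals and fitted must have equal length")
    if np.ptp(r) == 0 or np.ptp(f) == 0:
        return TestResult(name=name, statistic=0.0, df=float(len(r) - 2), p=1.0)
    rho, p = sps.spearmanr(r, f)
    return TestResult(name=name, statistic=float(rho), df=float(len(r) - 2),
                      p=float(min(max(p, 0.0), 1.0)))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment; output aligned with the input order.

    p_adj for the i-th smallest p is min over j >= i of m * p_(j) / j,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def adjust_family(results: list[TestResult]) -> list[TestResult]:
    """BH-adjust a family of TestResults in place (and return it)."""
    adj = benjamini_hochberg([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
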