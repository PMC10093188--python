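"""Cross-modality statistics on paired per-VOI parameter tables.

For each morphometric parameter the two modality branches are compared with
(a) a two-sided Mann–Whitney rank test on the two groups of per-VOI values
(exact enumeration for small untied samples, tie-corrected normal
approximation otherwise), and (b) a single linear regression with the
reference (hi-res) modality as the explanatory variable and the degraded
modality as the objective variable, with the F-test and coefficient of
determination R^2 of the fit. The rank test treats the groups as unpaired —
matching the original study design — even though VOIs are physically
paired; a sign-flip permutation alternative is available for sensitivity
checks but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RankTestResult",
    "RegressionResult",
    "ParameterComparison",
    "mann_whitney_u",
    "paired_signflip_test",
    "linear_regression_f",
    "compare_all",
]


@dataclass
class RankTestResult:
    U: float
    p: float
    n1: int
    n2: int
    method: Literal["exact", "normal_approx"]

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError(f"U={self.U} outside [0, n1*n2]")
        if not (0 < self.p <= 1):
            raise ValueError(f"p={self.p} outside (0, 1]")


@dataclass
class RegressionResult:
    intercept: float
    slope: float
    R2: float
    F: float
    p_F: float
    # parameters of the 95% confidence band for the mean response at x0:
    # yhat(x0) +/- t_crit * s * sqrt(1/n + (x0 - x_mean)^2 / Sxx)
    n: int
    x_mean: float
    Sxx: float
    resid_ms: float
    t_crit: float

    def confidence_band(self, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted mean and 95% band at the given explanatory values."""
        x0 = np.asarray(x0, dtype=float)
        yhat = self.intercept + self.slope * x0
        half = self.t_crit * np.sqrt(
            self.resid_ms * (1.0 / self.n + (x0 - self.x_mean) ** 2 / self.Sxx)
        )
        return yhat, yhat - half, yhat + half


@dataclass
class ParameterComparison:
    parameter: str
    x: np.ndarray  # hi-res per-VOI values
    y: np.ndarray  # degraded per-VOI values
    rank_test: RankTestResult | None
    regression: RegressionResult | None
    alpha: float = 0.05

    @property
    def x_mean_sd(self) -> tuple[float, float]:
        return float(np.mean(self.x)), float(np.std(self.x, ddof=1))

    @property
    def y_mean_sd(self) -> tuple[float, float]:
        return float(np.mean(self.y)), float(np.std(self.y, ddof=1))

    @property
    def significant(self) -> bool:
        return self.rank_test is not None and self.rank_test.p < self.alpha


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann–Whitney U test.

    Exact p by enumeration when both samples are small (n1 + n2 <= 20) and
    untied; otherwise the tie-corrected normal approximation with midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size <= 20) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        U=float(res.statistic),
        p=min(1.0, float(res.pvalue)),
        n1=x.size,
        n2=y.size,
        method="exact" if exact else "normal_approx",
    )


def paired_signflip_test(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Optional paired alternative: sign-flip permutation test on x - y.

    Exact enumeration of all 2^n sign patterns for n <= 12, otherwise Monte
    Carlo with ``n_perm`` draws. Returns the two-sided p-value.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("empty paired sample")
    obs = abs(d.mean())
    if n <= 12:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n)] for i in range(2**n)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
    stat = np.abs((signs * d).mean(axis=1))
    return float((stat >= obs - 1e-12).mean())


def linear_regression_f(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with F-test, R^2 and 95% band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("regression requires n >= 3 (F-test needs n - 2 > 0 d.f.)")
    if np.ptp(x) == 0:
        raise ValueError("explanatory variable is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid_ms = float(model.ssr / model.df_resid)
    sxx = float(((x - x.mean()) ** 2).sum())
    fval = float(model.fvalue)
    pf = float(model.f_pvalue)
    if math.isnan(fval):  # perfect fit: zero residual variance
        fval, pf = math.inf, 0.0
    return RegressionResult(
        intercept=float(intercept),
        slope=float(slope),
        R2=float(model.rsquared),
        F=fval,
        p_F=pf,
        n=n,
        x_mean=float(x.mean()),
        Sxx=sxx,
        resid_ms=resid_ms,
        t_crit=float(sps.t.ppf(0.975, n - 2)),
    )


def compare_all(
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
) -> tuple[list[ParameterComparison], pd.DataFrame, pd.DataFrame]:
    """Compare every parameter across modality branches.

    ``pairs`` must have columns ``branch`` ('hires'/'degraded'), ``voi`` and
    one column per parameter; VOIs must be common to both branches, with at
    least 3 of them. Returns the per-parameter comparisons plus two tidy
    DataFrames: a means table (mean ± sd per modality with the rank-test p,
    flagged at both the working and the strict significance level) and a
    regression table (slope, intercept, R^2, F, F-test p).
    """
    required = {"branch", "voi"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table must contain columns {sorted(required)}")
    hi = pairs[pairs["branch"] == "hires"].set_index("voi").sort_index()
    lo = pairs[pairs["branch"] == "degraded"].set_index("voi").sort_index()
    if not hi.index.equals(lo.index):
        raise ValueError("hires and degraded branches cover different VOIs")
    if len(hi) < 3:
        raise ValueError(f"need >= 3 paired VOIs, got {len(hi)}")
    params = [c for c in pairs.columns if c not in ("branch", "voi")]
    hi_params = set(hi.columns) - {"branch"}
    lo_params = set(lo.columns) - {"branch"}
    if hi_params != lo_params:
        raise ValueError("parameter sets differ between branches")

    comparisons: list[ParameterComparison] = []
    mean_rows, reg_rows = [], []
    for p in params:
        x = hi[p].to_numpy(dtype=float)
        y = lo[p].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        rank = reg = None
        if len(x) >= 3:
            rank = mann_whitney_u(x, y)
            try:
                reg = linear_regression_f(x, y)
            except ValueError:
                reg = None
        comp = ParameterComparison(parameter=p, x=x, y=y, rank_test=rank, regression=reg, alpha=alpha)
        comparisons.append(comp)
        xm, xs = comp.x_mean_sd if len(x) > 1 else (math.nan, math.nan)
        ym, ys = comp.y_mean_sd if len(y) > 1 else (math.nan, math.nan)
        mean_rows.append(
            {
                "parameter": p,
                "hires_mean": xm,
                "hires_sd": xs,
                "degraded_mean": ym,
                "degraded_sd": ys,
                "p_rank": rank.p if rank else math.nan,
                "significant": bool(rank and rank.p < alpha),
                "significant_strict": bool(rank and rank.p < strict_alpha),
                "n": len(x),
            }
        )
        reg_rows.append(
            {
                "parameter": p,
                "slope": reg.slope if reg else math.nan,
                "intercept": reg.intercept if reg else math.nan,
                "R2": reg.R2 if reg else math.nan,
                "F": reg.F if reg else math.nan,
                "p_F": reg.p_F if reg else math.nan,
                "F_significant": bool(reg and reg.p_F < alpha),
            }
        )
    return comparisons, pd.DataFrame(mean_rows), pd.DataFrame(reg_rows)
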