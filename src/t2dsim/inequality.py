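"""Regression-based inequality indices and agreement statistics.

RII/SII are computed on the ridit scale: each ordered group gets the
midpoint of its cumulative population share, and rates are regressed on
that score by weighted least squares (weights = shares).  SII is the
slope of the linear fit (absolute gap across the full spectrum); RII is
``exp(slope)`` of the log-linear fit, i.e. the ratio of predicted rates
at ridit 1 versus 0.  A Poisson-regression variant is available for
both.  Confidence intervals come from a nonparametric bootstrap over
group-level event counts when counts are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InequalityResult:
    rii: float
    sii: float
    rii_ci: tuple | None = None
    sii_ci: tuple | None = None
    floored: bool = False  # a zero rate was floored for the log fit


def ridit_scores(shares) -> np.ndarray:
    """Midpoints of cumulative shares for ordered groups."""
    shares = np.asarray(shares, dtype=float)
    if len(shares) < 2:
        raise ValueError("need >= 2 groups")
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    cum = np.concatenate([[0.0], np.cumsum(shares)])
    return (cum[:-1] + cum[1:]) / 2.0


def _wls_slope(x, y, w):
    w = np.asarray(w, dtype=float)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    return float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))


def _poisson_slope(x, y, w, log_link: bool):
    import statsmodels.api as sm

    fam = sm.families.Poisson() if log_link else sm.families.Poisson(sm.families.links.Identity())
    exog = sm.add_constant(np.asarray(x, dtype=float))
    model = sm.GLM(np.asarray(y, dtype=float), exog, family=fam, freq_weights=np.asarray(w))
    return float(model.fit().params[1])


def _indices(rates, shares, method, rate_floor):
    x = ridit_scores(shares)
    rates = np.asarray(rates, dtype=float)
    floored = bool((rates <= 0).any())
    safe = np.maximum(rates, rate_floor)
    if method == "wls":
        sii = _wls_slope(x, rates, shares)
        rii = float(np.exp(_wls_slope(x, np.log(safe), shares)))
    elif method == "poisson":
        sii = _poisson_slope(x, rates, shares, log_link=False)
        rii = float(np.exp(_poisson_slope(x, safe, shares, log_link=True)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return rii, sii, floored


def rii_sii(
    rates,
    shares,
    *,
    method: str = "wls",
    counts=None,
    denoms=None,
    n_boot: int = 200,
    seed=None,
    rate_floor: float = 1e-6,
) -> InequalityResult:
    """Relative and slope indices of inequality over ordered groups.

    Groups must be supplied in spectrum order (the regression runs from
    ridit 0 at the first group to 1 at the last).  Uniform rates give
    RII = 1 and SII = 0.  When per-group ``counts`` (events) and
    ``denoms`` (person-years) are given, 95% CIs are bootstrapped by
    resampling Poisson event counts per group.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    rii, sii, floored = _indices(rates, shares, method, rate_floor)

    rii_ci = sii_ci = None
    if counts is not None and denoms is not None:
        rng = np.random.default_rng(seed)
        counts = np.asarray(counts, dtype=float)
        denoms = np.asarray(denoms, dtype=float)
        riis, siis = [], []
        # resample event counts; rescale so bootstrap rates stay on the
        # caller's rate scale regardless of the denominators' units
        base = counts / denoms
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(base > 0, rates / np.where(base > 0, base, 1.0), 1.0)
        for _ in range(n_boot):
            c = rng.poisson(counts)
            r, s, _ = _indices(c / denoms * scale, shares, method, rate_floor)
            riis.append(r)
            siis.append(s)
        rii_ci = tuple(np.percentile(riis, [2.5, 97.5]))
        sii_ci = tuple(np.percentile(siis, [2.5, 97.5]))
    return InequalityResult(rii=rii, sii=sii, rii_ci=rii_ci, sii_ci=sii_ci, floored=floored)


def icc_agreement(x, y):
    """Two-way absolute-agreement single-measure ICC with F-based 95% CI.

    ``(icc, (lo, hi))`` for paired per-stratum series; requires >= 5 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired values")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both series; ICC undefined")
    import pingouin as pg

    n = len(x)
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["x", "y"], n),
            "score": np.concatenate([x, y]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement gives MSE = 0 inside the ANOVA; harmless here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(data=df, targets="target", raters="rater", ratings="score")
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci = row[ci_col]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))


def trend_test(years, values):
    """Slope and p-value of a linear time trend (OLS)."""
    import statsmodels.api as sm

    exog = sm.add_constant(np.asarray(years, dtype=float))
    fit = sm.OLS(np.asarray(values, dtype=float), exog).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def yearly_inequality(burden: pd.DataFrame, axis: str, outcome: str = "prevalence_rate",
                      method: str = "wls") -> pd.DataFrame:
    """RII/SII per simulated year along an ordered stratification axis.

    ``burden`` must contain finest-level rows (region x sex x education);
    the axis categories are aggregated with person-year weights.
    """
    from .constants import CATEGORY_ORDERS

    order = CATEGORY_ORDERS[axis]
    fine = burden[
        (burden["region"] != "All") & (burden["sex"] != "Both") & (burden["education"] != "All")
    ]
    count_col = {"prevalence_rate": "prevalent", "incidence_rate": "incident",
                 "daly_rate": "daly"}.get(outcome)
    out = []
    for year, sub in fine.groupby("year"):
        g = sub.groupby(axis)[["alive", count_col]].sum().reindex(order).dropna()
        if len(g) < 2:
            continue
        shares = (g["alive"] / g["alive"].sum()).to_numpy()
        rates = (g[count_col] / g["alive"] * 100_000).to_numpy()
        res = rii_sii(rates, shares, method=method)
        out.append({"year": year, "axis": axis, "outcome": outcome, "rii": res.rii, "sii": res.sii})
    return pd.DataFrame(out)
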