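"""Marginal effects of the fitted exposure polynomial across its distribution.

For the quadratic model with exposure centered at ``x0`` the marginal effect
at exposure level ``x`` is the partial derivative

    ME(x) = beta1 + 2 * beta2 * (x - x0)        [+ 3 * beta3 * (x - x0)^2]

so the linear coefficient *is* the marginal effect at ``x0``. Standard
errors come from the delta method: ``Var(ME) = g' V g`` with gradient
``g = (1, 2(x-x0)[, 3(x-x0)^2])`` over the exposure coefficients.
Confidence intervals use the normal 1.96 critical value; cluster counts in
intended use are large enough that the t/normal distinction is immaterial.

Percentile levels are computed once, on the pooled union of both outcome
samples *before* sibling/neighborhood group exclusions, and shared across
all models so that every model is evaluated at the same exposure levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILE_GRID = (1, 5, 10, 25, 50, 75, 90, 95, 99)
Z95 = 1.959963984540054


@dataclass
class MarginalEffect:
    percentile_label: str
    exposure_level: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """***p<0.01, **p<0.05, *p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def exposure_percentiles(values, grid=PERCENTILE_GRID) -> pd.Series:
    """Linear-interpolation percentiles of the pooled exposure distribution."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        raise ValueError("empty exposure pool")
    levels = np.percentile(v, grid, method="linear")
    return pd.Series(levels, index=[f"p{g}" for g in grid], name="exposure_level")


def _me_gradient(estimate, x: float, x0: float, group: int) -> pd.Series:
    """Gradient of ME(x) over the full coefficient vector.

    ``group=1`` adds the interaction derivatives (e.g. educated mothers);
    ``group=0`` is the baseline category.
    """
    d = x - x0
    g = pd.Series(0.0, index=estimate.params.index)
    g["pnm"] = 1.0
    g["pnm_sq"] = 2.0 * d
    if "pnm_cu" in g.index:
        g["pnm_cu"] = 3.0 * d ** 2
    if group:
        for prefix in ("education", "sex"):
            if f"{prefix}_x_pnm" in g.index:
                g[f"{prefix}_x_pnm"] = 1.0
                g[f"{prefix}_x_pnm_sq"] = 2.0 * d
                if f"{prefix}_x_pnm_cu" in g.index:
                    g[f"{prefix}_x_pnm_cu"] = 3.0 * d ** 2
    return g


def marginal_effect(estimate, x: float, x0: float | None = None,
                    label: str = "", group: int = 0) -> MarginalEffect:
    """Delta-method marginal effect of exposure at level ``x``.

    ``x0`` defaults to the centering value recorded in the estimate's spec.
    For interaction models ``group=1`` evaluates the indicated subgroup
    (interaction coefficients added in).
    """
    if not np.isfinite(x):
        raise ValueError("exposure level must be finite")
    if x0 is None:
        if estimate.spec is None:
            raise ValueError("x0 not given and estimate carries no spec")
        x0 = estimate.spec.centering_value
    g = _me_gradient(estimate, x, x0, group)
    est = float(g @ estimate.params)
    var = float(g @ estimate.vcov.to_numpy() @ g)
    se = np.sqrt(max(var, 0.0))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return MarginalEffect(
        percentile_label=label, exposure_level=float(x), estimate=est, se=se,
        ci_low=est - Z95 * se, ci_high=est + Z95 * se, p=p)


def effects_table(estimates: dict[str, object], percentiles: pd.Series,
                  x0: float | None = None, group: int = 0) -> pd.DataFrame:
    """Marginal effects of each model at each percentile (Table-3 shape)."""
    rows = []
    for model, est in estimates.items():
        for label, level in percentiles.items():
            me = marginal_effect(est, float(level), x0, label=label, group=group)
            rows.append({"model": model, "percentile": label,
                         "exposure_level": me.exposure_level,
                         "estimate": me.estimate, "se": me.se,
                         "ci_low": me.ci_low, "ci_high": me.ci_high,
                         "p": me.p, "stars": me.stars})
    return pd.DataFrame(rows)


def effects_curve(estimates: dict[str, object], percentiles: pd.Series,
                  x0: float | None = None, n_points: int = 101,
                  group: int = 0) -> pd.DataFrame:
    """Dense marginal-effect grid between percentile 5 and 95."""
    lo, hi = float(percentiles["p5"]), float(percentiles["p95"])
    xs = np.linspace(lo, hi, n_points)
    rows = []
    for model, est in estimates.items():
        for x in xs:
            me = marginal_effect(est, float(x), x0, group=group)
            rows.append({"model": model, "exposure_level": x,
                         "estimate": me.estimate, "se": me.se,
                         "ci_low": me.ci_low, "ci_high": me.ci_high})
    return pd.DataFrame(rows)
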