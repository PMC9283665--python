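"""Fixed-effects polynomial regressions with cluster-robust inference.

The outcome model is

    y_isnb = alpha + delta_s + beta1 * pnm + beta2 * pnm^2 [+ beta3 * pnm^3]
             + theta' x_i + eps_isnb

with ``pnm`` the exposure *centered at the 25th percentile of the pooled
exposure distribution before powers are formed*, so that beta1 is the
marginal effect at that percentile. ``delta_s`` are sibling (or
neighborhood, or survey) fixed effects, estimated by the within
transformation — numerically identical to one dummy per group. Standard
errors are Liang-Zeger cluster-robust at the primary-sampling-unit
(neighborhood) level with the CR1 small-sample factor
``G/(G-1) * (N-1)/(N-K)``. When the fixed-effect groups are nested inside
the clusters (siblings within a neighborhood, or the neighborhood itself),
the absorbed group dummies are not counted in K — the demeaning consumes
within-cluster degrees of freedom, so counting them would overstate the
variance roughly twofold for two-child sibling groups. When groups span
clusters (survey fixed effects) the dummies are counted. P-values use a t
reference with G-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

logger = logging.getLogger(__name__)

EXPOSURE_TERMS = ("pnm", "pnm_sq", "pnm_cu")


@dataclass
class RegressionSpec:
    """What to fit: outcome, fixed-effects level, polynomial, interaction."""

    outcome: str = "haz"
    fe_level: str = "sibling"
    polynomial_degree: int = 2
    interaction: str = "none"  # none | education | sex
    centering_value: float = 0.0
    estimator: str = "within_ols"  # within_ols | mundlak_logit

    def validate(self) -> None:
        if self.outcome not in ("haz", "school"):
            raise ValueError("outcome must be 'haz' or 'school'")
        if self.fe_level not in ("sibling", "neighborhood", "survey"):
            raise ValueError("unknown fe_level")
        if self.polynomial_degree not in (2, 3):
            raise ValueError("polynomial_degree must be 2 or 3")
        if self.interaction not in ("none", "education", "sex"):
            raise ValueError("unknown interaction")
        if self.estimator not in ("within_ols", "mundlak_logit"):
            raise ValueError("unknown estimator")
        if self.polynomial_degree == 3 and self.estimator != "within_ols":
            raise ValueError("cubic polynomial only supported with within_ols")
        if not np.isfinite(self.centering_value):
            raise ValueError("centering_value must be finite")


@dataclass
class FEEstimate:
    """Coefficients with cluster-robust covariance.

    ``params``/``vcov`` cover the reported (non-absorbed) terms; ``alpha``
    is the grand mean of the outcome — with mean-centered covariates and
    percentile-25-centered exposure it is the model constant. ``r_squared``
    is the overall R^2 of the equivalent dummy-variable regression;
    ``r_squared_within`` the R^2 of the demeaned fit.
    """

    params: pd.Series
    vcov: pd.DataFrame
    alpha: float
    n_obs: int
    n_groups: int
    n_clusters: int
    r_squared: float
    r_squared_within: float
    spec: RegressionSpec | None = None
    dropped_terms: list[str] = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        t = self.params / self.se
        df = max(self.n_clusters - 1, 1)
        return pd.Series(2.0 * stats.t.sf(np.abs(t), df), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        df = max(self.n_clusters - 1, 1)
        q = stats.t.ppf(0.5 + level / 2.0, df)
        se = self.se
        return pd.DataFrame({"low": self.params - q * se,
                             "high": self.params + q * se})

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "estimate": self.params, "se": self.se,
            "ci_low": ci["low"], "ci_high": ci["high"], "p": self.pvalues,
        })


def within_transform(values, groups) -> np.ndarray:
    """Subtract the group mean from each value (dummy-equivalent demeaning)."""
    v = np.asarray(values, dtype=float)
    g = pd.Series(np.asarray(groups))
    if v.ndim == 1:
        return v - g.map(pd.Series(v).groupby(g).mean()).to_numpy()
    df = pd.DataFrame(v)
    return (df - df.groupby(g.values).transform("mean")).to_numpy()


def build_design(records: pd.DataFrame, spec: RegressionSpec,
                 covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Exposure polynomial (centered first, then powered), interactions,
    covariates."""
    spec.validate()
    d = records["exposure"].to_numpy(float) - spec.centering_value
    x = pd.DataFrame(index=records.index)
    x["pnm"] = d
    x["pnm_sq"] = d ** 2
    if spec.polynomial_degree == 3:
        x["pnm_cu"] = d ** 3
    if spec.interaction != "none":
        flag_col = ("mother_any_education" if spec.interaction == "education"
                    else "female")
        e = records[flag_col].astype(float).to_numpy()
        x[f"{spec.interaction}_x_pnm"] = e * d
        x[f"{spec.interaction}_x_pnm_sq"] = e * d ** 2
        if spec.polynomial_degree == 3:
            x[f"{spec.interaction}_x_pnm_cu"] = e * d ** 3
        if spec.fe_level in ("neighborhood", "survey"):
            # the baseline indicator is constant within sibling groups and
            # enters only when the fixed effects do not absorb it
            x[spec.interaction] = e - e.mean()
    if covariates is not None:
        x = pd.concat([x, covariates], axis=1)
    return x


def _drop_collinear(X: np.ndarray, names: list[str],
                    tol: float = 1e-9) -> tuple[np.ndarray, list[str], list[str]]:
    """Rank-revealing pivoted QR; drops columns beyond the numerical rank."""
    if X.shape[1] == 0:
        return X, names, []
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
    if dropped:
        logger.warning("dropping collinear design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _cluster_sandwich(X: np.ndarray, resid: np.ndarray, clusters: np.ndarray,
                      n_absorbed: int) -> np.ndarray:
    """CR1 Liang-Zeger covariance; ``n_absorbed`` counts group dummies in K."""
    n, k = X.shape
    codes = pd.factorize(clusters)[0]
    g = codes.max() + 1
    if g < 2:
        raise ValueError("cluster-robust inference needs at least 2 clusters")
    xu = X * resid[:, None]
    scores = np.zeros((g, k))
    np.add.at(scores, codes, xu)
    meat = scores.T @ scores
    bread = np.linalg.inv(X.T @ X)
    kk = k + n_absorbed
    c = (g / (g - 1.0)) * ((n - 1.0) / max(n - kk, 1.0))
    return c * bread @ meat @ bread


def fit_fe_ols(spec: RegressionSpec, records: pd.DataFrame,
               covariates: pd.DataFrame | None = None,
               cluster_col: str = "neighborhood_id") -> FEEstimate:
    """Within-OLS fit of the exposure polynomial with CR1 cluster errors.

    ``records`` must carry ``outcome``, ``exposure``, ``group`` and the
    cluster column; ``covariates`` are additional design columns (already
    centered). Groups of size one must have been excluded upstream.
    """
    spec.validate()
    y = records["outcome"].to_numpy(float)
    groups = records["group"].to_numpy()
    X_df = build_design(records, spec, covariates)
    names = list(X_df.columns)
    Xw = within_transform(X_df.to_numpy(float), groups)
    yw = within_transform(y, groups)
    Xw, names, dropped = _drop_collinear(Xw, names)
    if Xw.shape[1] == 0:
        raise ValueError("empty design after collinearity drop")
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n_groups = pd.Series(groups).nunique()
    clusters = records[cluster_col].to_numpy()
    nested = (pd.DataFrame({"g": groups, "c": clusters})
              .groupby("g")["c"].nunique().max() == 1)
    vcov = _cluster_sandwich(Xw, resid, clusters,
                             n_absorbed=0 if nested else n_groups)
    ssr = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    tss_w = float((yw ** 2).sum())
    return FEEstimate(
        params=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        alpha=float(y.mean()),
        n_obs=len(y),
        n_groups=int(n_groups),
        n_clusters=int(pd.Series(records[cluster_col]).nunique()),
        r_squared=1.0 - ssr / tss if tss > 0 else np.nan,
        r_squared_within=1.0 - ssr / tss_w if tss_w > 0 else np.nan,
        spec=spec,
        dropped_terms=dropped,
    )


def fit_mundlak_logit(spec: RegressionSpec, records: pd.DataFrame,
                      covariates: pd.DataFrame | None = None,
                      cluster_col: str = "neighborhood_id") -> FEEstimate:
    """Correlated-random-effects logit: group means of all regressors added.

    Avoids the incidental-parameter problem of a dummy-per-group logit while
    controlling group-level confounding through the group means (Mundlak
    device). Cluster-robust covariance at the neighborhood level.
    """
    import statsmodels.api as sm

    spec.validate()
    y = records["outcome"].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("mundlak_logit requires a binary outcome")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logit fit refused")
    X_df = build_design(records, spec, covariates)
    groups = records["group"].to_numpy()
    means = X_df.groupby(groups).transform("mean")
    means.columns = [f"{c}_groupmean" for c in X_df.columns]
    full = pd.concat([X_df, means], axis=1)
    Xm, names, dropped = _drop_collinear(full.to_numpy(float), list(full.columns))
    Xc = np.column_stack([np.ones(len(y)), Xm])
    model = sm.Logit(y, Xc)
    res = model.fit(disp=False, maxiter=200,
                    cov_type="cluster",
                    cov_kwds={"groups": pd.factorize(records[cluster_col])[0]})
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logit did not converge: {res.mle_retvals}")
    idx = ["const"] + names
    return FEEstimate(
        params=pd.Series(res.params, index=idx),
        vcov=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
        alpha=float(res.params[0]),
        n_obs=len(y),
        n_groups=int(pd.Series(groups).nunique()),
        n_clusters=int(pd.Series(records[cluster_col]).nunique()),
        r_squared=float(res.prsquared),
        r_squared_within=np.nan,
        spec=spec,
        dropped_terms=dropped,
    )
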