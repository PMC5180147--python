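"""Per-bin regression of genus richness on sampling proxies, ranked by AICc.

Six candidate models of per-band genus richness G are fitted for each time
bin: G ~ TurtBF, G ~ TetBC, G ~ NMA, G ~ TurtBF + NMA, G ~ TetBC + NMA, and
an intercept-only null.  Fits are linear with iid Gaussian errors, estimated
by maximum likelihood (sigma2_hat = RSS/n), so that log-likelihoods are
comparable across fixed-effect structures:

    LL = -(n/2) * (ln(2*pi*sigma2_hat) + 1)

Model support uses the small-sample Akaike criterion

    AICc = -2 LL + 2k + 2k(k+1)/(n-k-1),

with k counting the fixed effects plus one residual-variance parameter, and
AICc = +inf when n - k - 1 <= 0 (the criterion is incalculable).  Akaike
weights renormalize exp(-dAICc/2) over finite-AICc models.  Explained
variation is the likelihood-based generalized R^2

    R^2 = 1 - exp(-(2/n) (LL_M - LL_0)),

the unscaled (Cox & Snell) form of Nagelkerke's statistic — the scaled
variant can exceed interpretable bounds for continuous Gaussian responses.
Model p-values come from a chi-square likelihood-ratio test against the
null with df = number of covariates, matching the ANOVA comparison of
nested ML fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .errors import ConfigurationError, ValidationError

#: The six candidate models, label -> covariate columns.
MODEL_SET: dict[str, tuple[str, ...]] = {
    "null": (),
    "TurtBF": ("TurtBF",),
    "TetBC": ("TetBC",),
    "NMA": ("NMA",),
    "TurtBF + NMA": ("TurtBF", "NMA"),
    "TetBC + NMA": ("TetBC", "NMA"),
}

_SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class GlsFit:
    """One maximum-likelihood linear fit (iid errors, no correlation structure)."""

    covariate_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    sigma2_ml: float
    ll: float
    k: int  # fixed effects + 1 variance parameter
    n: int
    degenerate: bool = False  # perfect fit: sigma2_ml ~ 0, LL reported +inf


def fit_linear_ml(y: Sequence[float] | pd.Series, X: pd.DataFrame | None = None) -> GlsFit:
    """ML fit of y on covariates X (intercept added; X=None gives the null model).

    Raises on collinear covariates (naming them) and when there are more
    parameters than observations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or X.shape[1] == 0:
        names: tuple[str, ...] = ()
        design = np.ones((n, 1))
    else:
        names = tuple(X.columns)
        design = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    p = design.shape[1]
    if n < p:
        raise ValidationError(f"{n} observations cannot identify {p} fixed effects")
    if np.linalg.matrix_rank(design) < p:
        raise ValidationError(f"collinear design: columns {('intercept',) + names}")

    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    sigma2 = rss / n
    if sigma2 < _SIGMA2_FLOOR:
        return GlsFit(names, np.asarray(fit.params), 0.0, float("inf"), p + 1, n, True)
    ll = float(fit.llf)  # OLS llf is exactly the ML Gaussian log-likelihood
    return GlsFit(names, np.asarray(fit.params), sigma2, ll, p + 1, n)


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; +inf when the correction term blows up."""
    if k < 1 or n < 1:
        raise ValidationError(f"invalid k={k}, n={n}")
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """exp(-dAICc/2) renormalized over finite-AICc models; infinite get 0."""
    values = np.asarray(aiccs, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValidationError("no finite AICc among candidate models")
    delta = values[finite] - values[finite].min()
    raw = np.exp(-delta / 2.0)
    weights = np.zeros_like(values)
    weights[finite] = raw / raw.sum()
    return weights


def generalized_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Likelihood-based R^2 = 1 - exp(-(2/n)(LL_M - LL_0)) (unscaled form)."""
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if ll_model < ll_null:
        warnings.warn(
            f"model log-likelihood {ll_model} below null {ll_null}; clamping R^2 at 0",
            stacklevel=2,
        )
        return 0.0
    if np.isinf(ll_model):
        return 1.0  # degenerate perfect fit; R^2 -> 1 in the limit
    return float(1.0 - np.exp(-(2.0 / n) * (ll_model - ll_null)))


def lrt_pvalue(ll_model: float, ll_null: float, df: int) -> float:
    """Chi-square LRT p-value of a model against the nested null."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    deviance = max(0.0, 2.0 * (ll_model - ll_null))
    return float(chi2.sf(deviance, df))


@dataclass
class ModelComparisonTable:
    """Six-row comparison for one time bin, sorted by AICc (inf rows last)."""

    bin_label: str
    table: pd.DataFrame  # columns: model, R2, p, AICc, dAICc, w, LL, k
    n: int
    dropped_bands: list[int]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in ("AICc", "dAICc"):
            out[col] = out[col].map(lambda v: "Inf" if np.isinf(v) else f"{v:.6g}")
        out[["R2", "p"]] = out[["R2", "p"]].astype(object)
        out.loc[out["model"] == "null", ["R2", "p"]] = ""
        out.to_csv(path, index=False)


def compare_models(
    band_data: pd.DataFrame,
    bin_label: str = "",
    models: Mapping[str, tuple[str, ...]] = MODEL_SET,
) -> ModelComparisonTable:
    """Fit and rank the candidate models for one bin's per-band table.

    ``band_data`` needs a ``G`` column plus every covariate used by
    ``models`` (default: TurtBF, TetBC, NMA).  Bands with a missing value in
    any used column are dropped complete-case and reported in
    ``dropped_bands`` — bands with no turtle occurrences are simply absent,
    not zero-filled.  Models that cannot be fitted (n - k - 1 <= 0) keep
    their row with AICc = +inf.
    """
    used_cols = sorted({c for cols in models.values() for c in cols})
    for col in ["G"] + used_cols:
        if col not in band_data.columns:
            raise ConfigurationError(f"band table lacks required column {col!r}")
    complete = band_data.dropna(subset=["G"] + used_cols)
    dropped = [i for i in band_data.index if i not in complete.index]
    n = len(complete)
    if n < 3:
        raise ValidationError(f"only {n} complete bands in bin {bin_label!r}; need >= 3")

    null_fit = fit_linear_ml(complete["G"])
    rows = []
    for label, cols in models.items():
        fit = null_fit if not cols else fit_linear_ml(complete["G"], complete[list(cols)])
        rows.append(
            {
                "model": label,
                "R2": np.nan if not cols else generalized_r2(fit.ll, null_fit.ll, n),
                "p": np.nan if not cols else lrt_pvalue(fit.ll, null_fit.ll, len(cols)),
                "AICc": aicc(fit.ll, fit.k, n),
                "LL": fit.ll,
                "k": fit.k,
            }
        )
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["w"] = akaike_weights(table["AICc"].to_numpy())
    table = table.sort_values(["AICc", "model"], kind="stable").reset_index(drop=True)
    table = table[["model", "R2", "p", "AICc", "dAICc", "w", "LL", "k"]]
    return ModelComparisonTable(bin_label, table, n, dropped)
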