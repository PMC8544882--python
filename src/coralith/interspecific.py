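"""Interspecific comparisons of biomass and pigment responses.

The comparison machinery used for species-level contrasts:

* one-way ANOVA on (natural-) log-transformed responses,
* Tukey-adjusted pairwise contrasts via the studentized-range distribution,
* Breusch-Pagan test of homogeneity of variance across species,
* Cook's-distance influence screening at the 4/n threshold, with an
  automatic refit excluding flagged points for side-by-side comparison,
* median +/- MAD summaries (MAD scaled by 1.4826 by default, the
  normal-consistency constant applied by most statistical environments).

The linear-model engine is statsmodels OLS; this module owns the transform
policy, the contrast construction and the reporting surface.

Responses containing exact zeros (chlorophyll *c* in skeletons dominated by
green algae) cannot be log-transformed directly.  The default policy is to
refuse with an explicit error so the caller can exclude the response; the
alternative ``zero_policy="half_min_offset"`` replaces exact zeros with half
of the smallest positive value before the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateFitError, DomainError, SchemaError

__all__ = [
    "ANOVAFit",
    "ContrastResult",
    "OutlierReport",
    "summarize_median_mad",
    "summarize_table",
    "fit_oneway_anova",
    "tukey_contrasts",
    "breusch_pagan",
    "cooks_outliers",
]

MAD_CONSTANT = 1.4826


def summarize_median_mad(
    values: Sequence[float], consistency_constant: float = MAD_CONSTANT
) -> tuple[float, float]:
    """Median and (scaled) median absolute deviation of a sample."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty sample")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)) * consistency_constant)
    return med, mad


def summarize_table(
    tidy: pd.DataFrame, *, consistency_constant: float = MAD_CONSTANT
) -> pd.DataFrame:
    """Median +/- MAD per species x response from a tidy table.

    Expects columns species, response_name, value.
    """
    for col in ("species", "response_name", "value"):
        if col not in tidy.columns:
            raise SchemaError(f"tidy response table is missing required column {col!r}")
    rows = []
    for (resp, sp), grp in tidy.groupby(["response_name", "species"], sort=True):
        med, mad = summarize_median_mad(grp["value"], consistency_constant)
        rows.append(
            {"response_name": resp, "species": sp, "median": med, "mad": mad, "n": len(grp)}
        )
    return pd.DataFrame(rows)


@dataclass
class ANOVAFit:
    """A fitted one-way ANOVA on the (possibly log-) transformed scale."""

    groups: list
    group_means: dict
    group_sizes: dict
    F: float
    p_F: float
    df_between: int
    df_residual: int
    sigma2: float
    residuals: np.ndarray
    log_transformed: bool
    ids: np.ndarray
    labels: np.ndarray
    values_t: np.ndarray  # transformed responses, model order
    sm_result: object = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.values_t)

    @property
    def k(self) -> int:
        return len(self.groups)


def _design_matrix(labels: np.ndarray, groups: list) -> np.ndarray:
    """Intercept + treatment dummies (first group as reference)."""
    X = np.ones((len(labels), len(groups)))
    for j, g in enumerate(groups[1:], start=1):
        X[:, j] = (labels == g).astype(float)
    return X


def fit_oneway_anova(
    samples: pd.DataFrame,
    *,
    log_transform: bool = True,
    zero_policy: str = "error",
    value_col: str = "value",
    group_col: str = "species",
    id_col: str = "specimen_id",
) -> ANOVAFit:
    """One-way ANOVA of a response across species.

    ``zero_policy``: "error" refuses non-positive values under the log
    transform; "half_min_offset" replaces exact zeros with half the minimum
    positive value (negatives always refuse).
    """
    for col in (group_col, value_col):
        if col not in samples.columns:
            raise SchemaError(f"grouped sample table is missing required column {col!r}")
    df = samples.copy().reset_index(drop=True)
    if id_col not in df.columns:
        df[id_col] = np.arange(len(df)).astype(str)
    labels = df[group_col].to_numpy()
    y = df[value_col].to_numpy(dtype=float)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise DomainError(f"need at least 2 groups for ANOVA, got {len(groups)}")
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, nsz in sizes.items() if nsz < 2]
    if small:
        raise DomainError(f"groups with fewer than 2 observations: {small}")
    if log_transform:
        if np.any(y < 0):
            raise DomainError("negative response values cannot be log-transformed")
        if np.any(y == 0):
            if zero_policy == "half_min_offset":
                pos = y[y > 0]
                if pos.size == 0:
                    raise DomainError("all response values are zero")
                y = np.where(y == 0, pos.min() / 2.0, y)
            else:
                raise DomainError(
                    "response contains exact zeros; exclude it from log-scale ANOVA or "
                    "pass zero_policy='half_min_offset'"
                )
        y = np.log(y)
    X = _design_matrix(labels, groups)
    res = sm.OLS(y, X).fit()
    scale = max(1.0, float(np.abs(y).max()))
    if not np.isfinite(res.mse_resid) or res.ssr <= (1e-12 * scale) ** 2 * len(y):
        raise DegenerateFitError(
            "zero within-group variance in every group: ANOVA is degenerate"
        )
    means = {g: float(y[labels == g].mean()) for g in groups}
    return ANOVAFit(
        groups=list(groups),
        group_means=means,
        group_sizes=sizes,
        F=float(res.fvalue),
        p_F=float(res.f_pvalue),
        df_between=len(groups) - 1,
        df_residual=int(res.df_resid),
        sigma2=float(res.mse_resid),
        residuals=np.asarray(res.resid),
        log_transformed=log_transform,
        ids=df[id_col].to_numpy(),
        labels=labels,
        values_t=y,
        sm_result=res,
    )


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple
    estimate: float  # difference of transformed group means
    se: float
    t: float
    p_adj: float
    df_residual: int
    df_between: int


def tukey_contrasts(fit: ANOVAFit) -> list[ContrastResult]:
    """All-pairs contrasts with Tukey honest-significant-difference p-values.

    For each unordered pair the t statistic uses the pooled residual variance;
    the adjusted p comes from the studentized-range distribution with
    ``(k, df_residual)``, evaluated at ``sqrt(2)*|t|``.
    """
    out = []
    for g1, g2 in combinations(fit.groups, 2):
        est = fit.group_means[g2] - fit.group_means[g1]
        se = float(
            np.sqrt(fit.sigma2 * (1.0 / fit.group_sizes[g1] + 1.0 / fit.group_sizes[g2]))
        )
        t = est / se
        p = float(
            stats.studentized_range.sf(np.sqrt(2.0) * abs(t), fit.k, fit.df_residual)
        )
        out.append(
            ContrastResult(
                pair=(g1, g2),
                estimate=float(est),
                se=se,
                t=float(t),
                p_adj=min(1.0, p),
                df_residual=fit.df_residual,
                df_between=fit.df_between,
            )
        )
    return out


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_1": [c.pair[0] for c in contrasts],
            "group_2": [c.pair[1] for c in contrasts],
            "estimate": [c.estimate for c in contrasts],
            "se": [c.se for c in contrasts],
            "t": [c.t for c in contrasts],
            "p_adj": [c.p_adj for c in contrasts],
            "df_between": [c.df_between for c in contrasts],
            "df_residual": [c.df_residual for c in contrasts],
        }
    )


def breusch_pagan(fit: ANOVAFit) -> tuple[float, int, float]:
    """Breusch-Pagan LM test of homoscedasticity across groups.

    The statistic is ``n * R^2`` of the auxiliary regression of squared
    residuals on the group design; df = k - 1.  Returns (lm, df, p).
    """
    if not np.any(fit.residuals != 0):
        raise DegenerateFitError("all residuals are zero; Breusch-Pagan is undefined")
    X = _design_matrix(fit.labels, fit.groups)
    lm, lm_p, _, _ = sm.stats.diagnostic.het_breuschpagan(fit.residuals, X)
    return float(lm), fit.k - 1, float(lm_p)


@dataclass
class OutlierReport:
    """Cook's-distance screen plus a refit excluding the flagged points."""

    threshold: float
    cooks_d: pd.Series  # indexed by observation id
    flagged: list  # (id, cooks_d) pairs, descending influence
    refit: object  # same type as the input fit, excluding flagged points (None if nothing flagged)
    comparison: pd.DataFrame  # side-by-side contrasts or coefficients


def cooks_outliers(fit, *, refit_factory=None) -> OutlierReport:
    """Flag influential observations with Cook's distance above 4/n.

    Works on any fit exposing a statsmodels OLS result (``sm_result``) and
    observation ids (``ids``) — one-way ANOVA fits and lognormal regression
    fits both qualify.  When points are flagged the model is automatically
    refitted without them and the contrast (or coefficient) tables are
    returned side by side, so the with/without comparison the screening
    protocol calls for is part of the report.
    """
    res = getattr(fit, "sm_result", None)
    if res is None:
        raise DomainError("fit does not expose a statsmodels result; cannot compute leverage")
    n, p = res.model.exog.shape
    if n <= p:
        raise DomainError(f"n ({n}) must exceed the number of parameters ({p})")
    d = res.get_influence().cooks_distance[0]
    threshold = 4.0 / n
    cooks = pd.Series(d, index=list(fit.ids), name="cooks_d")
    flagged_mask = d > threshold
    flagged = sorted(
        [(i, float(di)) for i, di in zip(fit.ids, d) if di > threshold],
        key=lambda t: -t[1],
    )
    refit = None
    if flagged and refit_factory is not None:
        refit = refit_factory(~flagged_mask)

    def _table(f, tag):
        if isinstance(f, ANOVAFit):
            tbl = contrasts_frame(tukey_contrasts(f))
        else:
            tbl = pd.DataFrame(
                {
                    "term": getattr(f, "param_names", [f"b{i}" for i in range(len(f.coefficients))]),
                    "estimate": f.coefficients,
                    "se": f.se,
                    "t": f.t,
                    "p": f.p,
                }
            )
        tbl = tbl.copy()
        tbl["model"] = tag
        return tbl

    if refit is not None:
        comparison = pd.concat(
            [_table(fit, "full"), _table(refit, "outliers_excluded")], ignore_index=True
        )
    else:
        comparison = _table(fit, "full")
    return OutlierReport(
        threshold=threshold, cooks_d=cooks, flagged=flagged, refit=refit, comparison=comparison
    )


def anova_outlier_report(
    samples: pd.DataFrame,
    *,
    log_transform: bool = True,
    zero_policy: str = "error",
    **kwargs,
) -> OutlierReport:
    """Convenience wrapper: fit, screen, and refit a one-way ANOVA."""
    fit = fit_oneway_anova(
        samples, log_transform=log_transform, zero_policy=zero_policy, **kwargs
    )

    def refit_without(keep_mask):
        kept = samples.reset_index(drop=True).loc[keep_mask]
        return fit_oneway_anova(
            kept, log_transform=log_transform, zero_policy=zero_policy, **kwargs
        )

    return cooks_outliers(fit, refit_factory=refit_without)
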