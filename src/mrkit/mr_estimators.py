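"""Causal effect estimation from harmonized summary statistics.

All estimators are weighted least-squares fits of per-SNP outcome effects on
exposure effects, with weights ``w_j = 1/se_outcome_j²``:

* **Wald ratio** — the per-SNP estimate ``β_Y/β_X`` with first-order
  (delta-method) standard error ``se_Y/|β_X|``, ignoring uncertainty in β_X
  as is standard for strong instruments.
* **IVW** — the regression through the origin; algebraically identical to
  the inverse-variance meta-analysis of the per-SNP Wald ratios. The
  intercept is constrained to zero, encoding the no-pleiotropy assumption.
* **MR-Egger** — the same regression with a free intercept. The intercept
  estimates the average directional pleiotropic effect per SNP; the slope is
  a pleiotropy-adjusted causal estimate. Exposure effects are oriented
  non-negative (with paired outcome sign flips) before fitting, the standard
  convention on which Egger's estimand depends.
* **Multivariable IVW** — joint regression on two exposures' effects, no
  intercept; each coefficient is that exposure's direct effect conditional
  on the other.

Standard errors use either fixed-effect weights or (the default)
multiplicative random effects: the fixed-effect SE is scaled by the residual
standard deviation of the weighted regression, floored at 1 so that
underdispersion never *shrinks* an SE. Point estimates are identical under
the two weighting models. 95% intervals use the normal quantile 1.96 and
p-values are two-sided normal, throughout.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    RankDeficiencyError,
    ScaleMisuseError,
)
from .harmonize import HarmonizedDataset

#: Normal quantile used for all 95% confidence intervals (documented constant).
Z95 = 1.96

#: Condition-number ceiling above which the multivariable design is declared
#: collinear rather than silently splitting an effect between exposures.
_COND_LIMIT = 1e8


@dataclasses.dataclass
class MREstimate:
    """A causal effect estimate with its uncertainty.

    ``beta`` is per SD of the exposure, on the outcome's scale (SD units for
    continuous outcomes, log odds ratio for binary outcomes).
    """

    method: str
    exposure: str | tuple[str, ...]
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    weights_model: str
    outcome_type: str = "continuous"


@dataclasses.dataclass
class EggerResult:
    """MR-Egger slope plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclasses.dataclass
class OddsScaleSummary:
    """An estimate re-expressed as an odds ratio per SD of exposure."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    percent_change: float  # (1 - OR) * 100; positive = lower odds
    text: str


def _finish(beta: float, se: float) -> tuple[float, float, float]:
    z = beta / se
    pval = 2.0 * stats.norm.sf(abs(z))
    return beta - Z95 * se, beta + Z95 * se, pval


def wald_ratio(row, outcome_name: str = "", outcome_type: str = "continuous") -> MREstimate:
    """Per-SNP causal estimate: ``β_Y/β_X`` with first-order SE ``se_Y/|β_X|``.

    ``row`` is a mapping with ``beta_exposure``, ``beta_outcome``,
    ``se_outcome`` (a row of :attr:`HarmonizedDataset.df` works directly).
    """
    bx = float(row["beta_exposure"])
    by = float(row["beta_outcome"])
    sey = float(row["se_outcome"])
    if bx == 0:
        raise DegenerateDesignError(
            f"Wald ratio undefined for SNP {row.get('snp_id', '?')}: beta_exposure = 0"
        )
    beta = by / bx
    se = sey / abs(bx)
    lo, hi, p = _finish(beta, se)
    return MREstimate(
        method="wald",
        exposure=str(row.get("exposure", "")),
        outcome=outcome_name,
        beta=beta, se=se, ci_low=lo, ci_high=hi, pval=p,
        n_snps=1, weights_model="fixed", outcome_type=outcome_type,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, weights_model: str):
    """Weighted least squares via the normal equations.

    Returns (theta, se_vector) where the SEs are fixed-effect or scaled by
    ``max(1, residual SD)`` under multiplicative random effects.
    """
    n, p = X.shape
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    A = Xw.T @ Xw
    theta = np.linalg.solve(A, Xw.T @ yw)
    cov_fixed = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_fixed))
    if weights_model == "multiplicative_random":
        if n <= p:
            raise InsufficientDataError(
                f"multiplicative random effects needs > {p} SNPs (got {n})"
            )
        resid = yw - Xw @ theta
        sigma2 = float(resid @ resid) / (n - p)
        se = se * math.sqrt(max(1.0, sigma2))  # floored: no gain from underdispersion
    elif weights_model != "fixed":
        raise ValueError(f"unknown weights_model {weights_model!r}")
    return theta, se


def ivw(
    dataset: HarmonizedDataset,
    weights_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate for a single exposure.

    Weighted regression of outcome betas on exposure betas through the
    origin: ``beta = Σ w_j β_Xj β_Yj / Σ w_j β_Xj²`` with ``w_j = 1/se_Yj²``.
    """
    if dataset.n_exposures != 1:
        raise ValueError("ivw() is univariable; use mvmr_ivw() for two exposures")
    bx = dataset.df["beta_exposure"].to_numpy(float)
    by = dataset.df["beta_outcome"].to_numpy(float)
    sey = dataset.df["se_outcome"].to_numpy(float)
    if len(bx) < 1:
        raise InsufficientDataError("ivw needs at least 1 SNP")
    if np.all(bx == 0):
        raise DegenerateDesignError("all exposure betas are zero")
    w = 1.0 / sey**2
    theta, se = _wls(bx[:, None], by, w, weights_model)
    beta, sebeta = float(theta[0]), float(se[0])
    lo, hi, p = _finish(beta, sebeta)
    return MREstimate(
        method="ivw_mre" if weights_model == "multiplicative_random" else "ivw_fe",
        exposure=dataset.exposure_names[0],
        outcome=dataset.outcome_name,
        beta=beta, se=sebeta, ci_low=lo, ci_high=hi, pval=p,
        n_snps=len(bx),
        weights_model="multiplicative_random" if weights_model == "multiplicative_random" else "fixed",
        outcome_type=dataset.outcome_type,
    )


def egger(dataset: HarmonizedDataset) -> EggerResult:
    """MR-Egger regression (free intercept; slope adjusted for directional
    pleiotropy; intercept = average pleiotropic effect per SNP).

    Exposure betas are oriented non-negative before fitting, flipping the
    paired outcome beta's sign; results are invariant to the input
    orientation given this convention.
    """
    if dataset.n_exposures != 1:
        raise ValueError("egger() is univariable")
    df = dataset.df
    if len(df) < 3:
        raise InsufficientDataError(f"MR-Egger needs >= 3 SNPs (got {len(df)})")
    bx = df["beta_exposure"].to_numpy(float).copy()
    by = df["beta_outcome"].to_numpy(float).copy()
    sey = df["se_outcome"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sey**2
    X = np.column_stack([np.ones_like(bx), bx])
    theta, se = _wls(X, by, w, "multiplicative_random")
    slope, slope_se = float(theta[1]), float(se[1])
    icpt, icpt_se = float(theta[0]), float(se[0])
    lo, hi, p = _finish(slope, slope_se)
    _, _, icpt_p = _finish(icpt, icpt_se)
    return EggerResult(
        slope=MREstimate(
            method="egger_slope",
            exposure=dataset.exposure_names[0],
            outcome=dataset.outcome_name,
            beta=slope, se=slope_se, ci_low=lo, ci_high=hi, pval=p,
            n_snps=len(df), weights_model="multiplicative_random",
            outcome_type=dataset.outcome_type,
        ),
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_pval=icpt_p,
    )


def mvmr_ivw(
    dataset: HarmonizedDataset,
    weights_model: str = "multiplicative_random",
) -> tuple[MREstimate, MREstimate]:
    """Multivariable IVW: joint no-intercept WLS on both exposures' betas.

    Each coefficient is the direct effect of that exposure conditional on
    the other. An (effectively) collinear exposure-beta design raises
    :class:`RankDeficiencyError` reporting the condition number.
    """
    if dataset.n_exposures != 2:
        raise ValueError("mvmr_ivw() needs a 2-exposure dataset")
    df = dataset.df
    if len(df) < 3:
        raise InsufficientDataError(f"multivariable IVW needs >= 3 SNPs (got {len(df)})")
    X = dataset.exposure_betas()
    by = df["beta_outcome"].to_numpy(float)
    sey = df["se_outcome"].to_numpy(float)
    w = 1.0 / sey**2
    zero_cols = [k for k in range(X.shape[1]) if np.all(X[:, k] == 0)]
    if len(zero_cols) == X.shape[1]:
        raise DegenerateDesignError("all exposure betas are zero")
    if zero_cols:
        # Degenerate reduction: an exposure with no instrument effects
        # contributes nothing; the other coefficient equals its univariable
        # estimate and the zero column's effect is unidentified.
        keep = [k for k in range(X.shape[1]) if k not in zero_cols]
        theta_k, se_k = _wls(X[:, keep], by, w, weights_model)
        theta = np.zeros(X.shape[1])
        se = np.full(X.shape[1], np.inf)
        theta[keep], se[keep] = theta_k, se_k
    else:
        Xw = X * np.sqrt(w)[:, None]
        cond = float(np.linalg.cond(Xw))
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise RankDeficiencyError(
                f"exposure-beta design is collinear (condition number {cond:.3g})",
                condition_number=cond,
            )
        theta, se = _wls(X, by, w, weights_model)
    wm = "multiplicative_random" if weights_model == "multiplicative_random" else "fixed"
    out = []
    for k, name in enumerate(dataset.exposure_names):
        lo, hi, p = _finish(float(theta[k]), float(se[k]))
        out.append(
            MREstimate(
                method="mvmr_ivw",
                exposure=name,
                outcome=dataset.outcome_name,
                beta=float(theta[k]), se=float(se[k]),
                ci_low=lo, ci_high=hi, pval=p,
                n_snps=len(df), weights_model=wm,
                outcome_type=dataset.outcome_type,
            )
        )
    return tuple(out)


def to_odds_scale(est: MREstimate) -> OddsScaleSummary:
    """Re-express a log-OR estimate as an odds ratio with 95% CI.

    Reports the percent change in odds per SD of exposure, phrased as
    "% lower" when OR < 1 (rounded to the nearest integer in the text; the
    numeric fields carry full precision).
    """
    if est.outcome_type != "binary":
        raise ScaleMisuseError(
            f"odds-scale conversion requires a binary outcome (got {est.outcome_type!r})"
        )
    orr = math.exp(est.beta)
    lo, hi = math.exp(est.ci_low), math.exp(est.ci_high)
    pct = (1.0 - orr) * 100.0
    if orr < 1:
        text = (
            f"{round(pct)}% (95% CI: {round((1 - hi) * 100)}-{round((1 - lo) * 100)}%) "
            f"lower odds per SD"
        )
    else:
        text = f"OR = {orr:.2f} (95% CI: {lo:.2f}-{hi:.2f}) per SD"
    return OddsScaleSummary(odds_ratio=orr, ci_low=lo, ci_high=hi,
                            percent_change=pct, text=text)
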