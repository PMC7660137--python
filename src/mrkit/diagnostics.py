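"""Instrument validity and sensitivity diagnostics.

* per-SNP variance explained (r²), by allele frequency + beta for traits in
  SD units, or from the t statistic when only beta/se/n are available;
* Steiger directionality filtering: a SNP whose estimated r² on the outcome
  exceeds its r² on the exposure is evidence the hypothesized causal
  direction is wrong for that SNP; filtering is the plain r² comparison (not
  a significance threshold), with the two-sample Steiger z test reported
  alongside;
* instrument-strength F statistic from total r², sample size and instrument
  count, with the conventional F > 10 weak-instrument flag;
* Cochran's Q heterogeneity over per-SNP Wald ratios, with first-order
  (delta-method) weights matching the IVW weighting;
* leave-one-out re-estimation and funnel-plot data with a precision-weighted
  asymmetry summary.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientDataError, MRKitError
from .harmonize import HarmonizedDataset
from .mr_estimators import MREstimate, ivw

R2_METHODS = ("eaf_beta", "t_stat")


@dataclasses.dataclass
class SteigerRecord:
    """Per-SNP variance explained in exposure vs outcome and the verdict."""

    snp_id: str
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    z_steiger: float | None = None
    steiger_pval: float | None = None


@dataclasses.dataclass
class QResult:
    Q: float
    df: int
    pval: float


@dataclasses.dataclass
class InstrumentStrength:
    r2_total: float
    n: int
    k: int
    F: float
    weak: bool


@dataclasses.dataclass
class LeaveOneOutResult:
    """One re-estimate per omitted SNP, plus influence flags."""

    estimates: list[tuple[str, MREstimate]]
    full: MREstimate
    flagged: list[str]  # omissions shifting the estimate > threshold·SE or flipping sign

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "omitted_snp": snp,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "influential": snp in self.flagged,
            }
            for snp, e in self.estimates
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass
class FunnelResult:
    """Per-SNP Wald estimates vs precision, with an asymmetry summary.

    The asymmetry summary is a precision-weighted regression of the per-SNP
    estimate on its precision (weights 1/se_wald², free intercept); a slope
    near zero indicates symmetry, i.e. no small-study-like relation between
    effect and precision. Undefined (None) with fewer than 3 SNPs.
    """

    table: pd.DataFrame  # columns: snp_id, wald_ratio, precision
    asymmetry_slope: float | None
    asymmetry_se: float | None
    asymmetry_pval: float | None


def snp_r2(
    beta: float,
    se: float | None = None,
    eaf: float | None = None,
    n: float | None = None,
    method: str = "eaf_beta",
) -> float:
    """Proportion of trait variance explained by one SNP.

    ``eaf_beta`` (trait in SD units, EAF available):
    ``r² = 2·eaf·(1−eaf)·beta²`` — the variance of the per-allele genetic
    value under Hardy–Weinberg. ``t_stat``: with ``t = beta/se``,
    ``r² = t²/(t² + n − 2)``.
    """
    if method == "eaf_beta":
        if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)):
            raise ConfigurationError("snp_r2(method='eaf_beta') requires EAF")
        if not (0 < eaf < 1):
            raise ConfigurationError(f"EAF out of (0,1): {eaf}")
        return 2.0 * eaf * (1.0 - eaf) * beta**2
    if method == "t_stat":
        if se is None or n is None or (isinstance(n, float) and math.isnan(n)):
            raise ConfigurationError("snp_r2(method='t_stat') requires se and n")
        if n <= 2:
            raise ConfigurationError(f"t_stat method needs n > 2 (got {n})")
        t2 = (beta / se) ** 2
        return t2 / (t2 + n - 2.0)
    raise ConfigurationError(f"unknown r² method {method!r}; choose from {R2_METHODS}")


def _row_r2(beta, se, eaf, n, method, snp_id, side):
    try:
        return snp_r2(beta, se, eaf, n, method)
    except ConfigurationError as exc:
        raise MRKitError(f"r² undefined for SNP {snp_id} ({side}): {exc}") from exc


def steiger_filter(
    dataset: HarmonizedDataset,
    r2_method: str = "eaf_beta",
    compute_test: bool = True,
) -> tuple[list[SteigerRecord], HarmonizedDataset]:
    """Directionality filter: keep SNPs explaining more variance in the
    exposure than in the outcome.

    The optional z test is the two-independent-sample comparison of the
    implied correlations ``r = sqrt(r²)`` after Fisher transformation:
    ``z = (z_exp − z_out) / sqrt(1/(n_exp−3) + 1/(n_out−3))`` with a
    two-sided p-value. Filtering itself uses only the r² comparison.
    Idempotent: filtering a filtered dataset removes nothing.
    """
    if dataset.n_exposures != 1:
        raise ValueError("steiger_filter expects a single-exposure dataset")
    records: list[SteigerRecord] = []
    keep: list[str] = []
    for _, row in dataset.df.iterrows():
        snp = row["snp_id"]
        r2_exp = _row_r2(row["beta_exposure"], row["se_exposure"], row["eaf_exposure"],
                         row.get("n_exposure"), r2_method, snp, "exposure")
        r2_out = _row_r2(row["beta_outcome"], row["se_outcome"], row["eaf_outcome"],
                         row.get("n_outcome"), r2_method, snp, "outcome")
        ok = bool(r2_exp > r2_out)
        z = p = None
        if compute_test:
            n_exp, n_out = row.get("n_exposure"), row.get("n_outcome")
            if (
                n_exp is not None and n_out is not None
                and not (math.isnan(n_exp) or math.isnan(n_out))
                and n_exp > 3 and n_out > 3
            ):
                z_exp = np.arctanh(min(math.sqrt(r2_exp), 1 - 1e-15))
                z_out = np.arctanh(min(math.sqrt(r2_out), 1 - 1e-15))
                denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
                z = float((z_exp - z_out) / denom)
                p = float(2.0 * stats.norm.sf(abs(z)))
        records.append(SteigerRecord(snp, r2_exp, r2_out, ok, z, p))
        if ok:
            keep.append(snp)
    return records, dataset.subset(keep)


def steiger_records_frame(records: list[SteigerRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def f_statistic(r2_total: float, n: int, k: int) -> InstrumentStrength:
    """Instrument-strength F from total variance explained.

    ``F = (r²/(1−r²)) · ((n − 1 − k)/k)``; F ≤ 10 is flagged as weak by the
    usual rule of thumb.
    """
    if not (0 <= r2_total < 1):
        raise ConfigurationError(f"r2_total must be in [0, 1): {r2_total}")
    if k < 1 or n <= k + 1:
        raise ConfigurationError(f"need n > k + 1 >= 2 (got n={n}, k={k})")
    F = (r2_total / (1.0 - r2_total)) * ((n - 1.0 - k) / k)
    return InstrumentStrength(r2_total=r2_total, n=n, k=k, F=F, weak=F <= 10)


def _wald_terms(dataset: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their inverse first-order variances."""
    bx = dataset.df["beta_exposure"].to_numpy(float)
    by = dataset.df["beta_outcome"].to_numpy(float)
    sey = dataset.df["se_outcome"].to_numpy(float)
    if np.any(bx == 0):
        bad = dataset.df.loc[bx == 0, "snp_id"].tolist()
        raise MRKitError(f"Wald ratio undefined (beta_exposure = 0) for SNPs {bad}")
    b = by / bx
    w = bx**2 / sey**2
    return b, w


def cochrans_q(dataset: HarmonizedDataset, est: MREstimate | None = None) -> QResult:
    """Cochran's Q heterogeneity of per-SNP Wald ratios about the IVW fit.

    ``Q = Σ w_j (b_j − β_IVW)²`` with first-order Wald-ratio weights
    (identical to the IVW weighting); p from χ² with ``n_snps − 1`` df.
    When ``est`` is omitted the fixed-effect IVW estimate is used, the
    classical reference point for Q.
    """
    if dataset.n_snps < 2:
        raise InsufficientDataError("Cochran's Q needs >= 2 SNPs")
    b, w = _wald_terms(dataset)
    beta = est.beta if est is not None else ivw(dataset, "fixed").beta
    Q = float(np.sum(w * (b - beta) ** 2))
    df = dataset.n_snps - 1
    return QResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))


def leave_one_out(
    dataset: HarmonizedDataset,
    weights_model: str = "multiplicative_random",
    influence_se_multiple: float = 1.0,
) -> LeaveOneOutResult:
    """Re-estimate IVW omitting one SNP at a time.

    An omission is flagged influential when the estimate moves by more than
    ``influence_se_multiple`` full-sample *fixed-effect* SEs or changes sign
    — a numeric proxy for the visual distortion check on leave-one-out
    plots. The fixed-effect SE is the yardstick because it measures the
    information in the data; an outlier inflates the random-effects SE and
    would otherwise mask its own influence.
    """
    if dataset.n_snps < 3:
        raise InsufficientDataError("leave-one-out needs >= 3 SNPs")
    full = ivw(dataset, weights_model)
    scale_se = ivw(dataset, "fixed").se
    snps = dataset.df["snp_id"].tolist()
    estimates: list[tuple[str, MREstimate]] = []
    flagged: list[str] = []
    for snp in snps:
        reduced = dataset.subset([s for s in snps if s != snp])
        e = ivw(reduced, weights_model)
        estimates.append((snp, e))
        sign_change = np.sign(e.beta) != np.sign(full.beta) and full.beta != 0
        if abs(e.beta - full.beta) > influence_se_multiple * scale_se or sign_change:
            flagged.append(snp)
    return LeaveOneOutResult(estimates=estimates, full=full, flagged=flagged)


def funnel_data(dataset: HarmonizedDataset) -> FunnelResult:
    """Per-SNP Wald estimate and precision (1/se_wald), plus asymmetry."""
    if dataset.n_snps < 1:
        raise InsufficientDataError("funnel_data needs >= 1 SNP")
    b, w = _wald_terms(dataset)
    precision = np.sqrt(w)  # 1 / se_wald
    table = pd.DataFrame(
        {"snp_id": dataset.df["snp_id"], "wald_ratio": b, "precision": precision}
    )
    if dataset.n_snps < 3:
        return FunnelResult(table, None, None, None)
    X = np.column_stack([np.ones_like(precision), precision])
    sw = precision  # weight sqrt = 1/se
    Xw, yw = X * sw[:, None], b * sw
    A = Xw.T @ Xw
    theta = np.linalg.solve(A, Xw.T @ yw)
    resid = yw - Xw @ theta
    sigma2 = float(resid @ resid) / (len(b) - 2)
    cov = np.linalg.inv(A) * max(1.0, sigma2)
    slope, slope_se = float(theta[1]), float(math.sqrt(cov[1, 1]))
    pval = float(2.0 * stats.norm.sf(abs(slope / slope_se)))
    return FunnelResult(table, slope, slope_se, pval)
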