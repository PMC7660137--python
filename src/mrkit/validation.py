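"""Estimator validation against the causal-scenario generator.

Two harnesses used by the test suite and the reproduction script:

* :func:`scenario_validation` — replicated simulation of the library
  scenarios (confounding, mediation, disconnected traits, joint effects),
  recording for every replicate the univariable and multivariable estimates
  for both exposures, whether each nominal 95% CI covers the implied truth
  (where the panel's per-SNP truth is well defined), and whether zero is
  rejected. The qualitative verdict table — univariable effects non-null
  where the causal diagram implies them, multivariable direct effects
  consistent with zero where it says "no independent effect" — is then a
  set of rejection-rate summaries, and CI calibration is the pooled
  coverage across all defined-truth estimands.

* :func:`replica_analysis` — the full pipeline on the synthetic replica of
  the education/intelligence/AD study design (see
  :func:`mrkit.synthetic_gwas.replica_study_config`), returning the
  headline quantities on the scales usually reported (SD units,
  percent-lower odds, counts).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .harmonize import HarmonizedDataset, build_mvmr_dataset, harmonize_pair
from .mr_estimators import ivw, mvmr_ivw
from .pipeline import run_simulated_study
from .synthetic_gwas import (
    AD,
    EA,
    IQ,
    make_two_sample_study,
    replica_study_config,
    scenario_config,
)

#: Which estimands the causal diagrams declare null ("no independent
#: effect") vs non-null, per scenario. `uni_ea` is the univariable EA→AD
#: IVW on the EA panel, `mv_ea` the multivariable direct effect, etc.
SCENARIO_VERDICTS: dict[str, dict[str, bool]] = {
    # confounding of the EA–AD association by IQ
    "a": {"uni_ea": True, "uni_iq": True, "mv_ea": False, "mv_iq": True},
    # full mediation of EA's effect through IQ
    "c": {"uni_ea": True, "uni_iq": True, "mv_ea": False, "mv_iq": True},
    # genetically driven but causally disconnected traits: nothing real
    "g": {"uni_ea": False, "uni_iq": False, "mv_ea": False, "mv_iq": False},
    # joint direct effects of both exposures (reciprocal EA<->IQ)
    "h": {"uni_ea": True, "uni_iq": True, "mv_ea": True, "mv_iq": True},
}


def _replicate_estimates(study) -> list[dict]:
    """The four AD-side estimands of one simulated study."""
    truth = study.truth
    rows = []
    uni = {}
    for short, trait, panel in (("uni_ea", EA, study.panels[EA]),
                                ("uni_iq", IQ, study.panels[IQ])):
        ds = harmonize_pair(study.instruments(trait), study.outcome_tables[AD])
        est = ivw(ds)
        value, homogeneous = truth.implied_ivw(panel, trait, AD)
        uni[short] = est
        rows.append(
            {"estimand": short, "est": est.beta, "se": est.se,
             "truth": value if homogeneous else np.nan,
             "rejected": est.pval < 0.05}
        )
    mv_ds = build_mvmr_dataset(
        study.instruments(EA), study.instruments(IQ),
        {EA: study.exposure_tables[EA], IQ: study.exposure_tables[IQ]},
        study.outcome_tables[AD],
    )
    mv_ea, mv_iq = mvmr_ivw(mv_ds)
    for short, est, tr in (("mv_ea", mv_ea, truth.mvmr_direct[0]),
                           ("mv_iq", mv_iq, truth.mvmr_direct[1])):
        rows.append(
            {"estimand": short, "est": est.beta, "se": est.se, "truth": tr,
             "rejected": est.pval < 0.05}
        )
    for row in rows:
        if np.isnan(row["truth"]):
            row["covered"] = np.nan
        else:
            lo, hi = row["est"] - 1.96 * row["se"], row["est"] + 1.96 * row["se"]
            row["covered"] = float(lo <= row["truth"] <= hi)
    return rows


def scenario_validation(
    scenario_ids=("a", "c", "g", "h"),
    n_replicates: int = 200,
    seed: int = 20200131,
    **config_overrides,
) -> pd.DataFrame:
    """Replicated scenario runs; one row per (scenario, replicate, estimand).

    Default study conditions: the library's designed panels (100
    instruments for scenarios c/g/h), 20 000 individuals per sample.
    """
    records = []
    for s_idx, sid in enumerate(scenario_ids):
        for rep in range(n_replicates):
            rep_seed = (seed + 100_003 * s_idx + rep) % (2**31 - 1)
            cfg = scenario_config(sid, selection="oracle", seed=rep_seed,
                                  **config_overrides)
            study = make_two_sample_study(cfg)
            for row in _replicate_estimates(study):
                records.append({"scenario": sid, "replicate": rep, **row})
    return pd.DataFrame(records)


def summarize_validation(frame: pd.DataFrame) -> dict:
    """Rejection rates per (scenario, estimand) plus pooled CI coverage."""
    out: dict = {"rejection_rate": {}, "mean_estimate": {}}
    for (sid, est), grp in frame.groupby(["scenario", "estimand"]):
        out["rejection_rate"][(sid, est)] = float(grp["rejected"].mean())
        out["mean_estimate"][(sid, est)] = float(grp["est"].mean())
    defined = frame.dropna(subset=["covered"])
    out["pooled_coverage"] = float(defined["covered"].mean())
    out["n_coverage_checks"] = int(len(defined))
    return out


def summary_level_dataset(bx, by, sey) -> HarmonizedDataset:
    """A harmonized dataset built directly from summary-level arrays (no
    individual-level simulation) — for estimator calibration studies."""
    k = len(bx)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "chrom": "1",
            "pos": np.arange(1, k + 1) * 1_000_000,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exposure": np.asarray(bx, float),
            "se_exposure": 0.01,
            "eaf_exposure": 0.3,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sey, float),
            "eaf_outcome": 0.3,
            "n_exposure": 100_000.0,
            "n_outcome": 50_000.0,
            "flag": "unchanged",
        }
    )
    return HarmonizedDataset(("exposure",), "outcome", "continuous", df,
                             df.iloc[0:0][["snp_id", "flag"]])


def q_null_calibration(n_replicates: int = 1000, seed: int = 20200131,
                       n_snps: int = 12, theta: float = 0.25) -> float:
    """Cochran's-Q rejection rate at α=0.05 under homogeneous effects with
    correctly specified outcome SEs (should be ≈ 0.05)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        bx = rng.uniform(0.05, 0.3, n_snps)
        sey = rng.uniform(0.01, 0.03, n_snps)
        by = theta * bx + rng.normal(0, sey)
        q = dx.cochrans_q(summary_level_dataset(bx, by, sey))
        rejections += q.pval < 0.05
    return rejections / n_replicates


def replica_analysis(seed: int = 20200131, **overrides) -> dict:
    """Full pipeline on the synthetic study replica; headline quantities.

    Returned values are on the scales usually reported: SD units for the
    exposure↔exposure effects, percent-lower odds of AD per SD for the
    univariable and multivariable AD effects, counts for the Steiger
    bookkeeping, and instrument-strength F statistics from the estimated
    per-SNP variance explained.
    """
    cfg = replica_study_config(seed=seed, **overrides)
    run = run_simulated_study(cfg, sensitivity=True)
    fwd, rev = run.bidirectional.forward, run.bidirectional.reverse
    uni_ea, uni_iq = run.ad.uni[EA], run.ad.uni[IQ]
    mv_ea, mv_iq = run.ad.mvmr

    def _f_stat(res):
        ds = res.dataset.df
        r2 = float(np.sum(2 * ds["eaf_exposure"] * (1 - ds["eaf_exposure"])
                          * ds["beta_exposure"] ** 2))
        return dx.f_statistic(r2, int(ds["n_exposure"].iloc[0]), len(ds))

    q_pvals = {
        "bidirectional_forward": fwd.q.pval,
        "bidirectional_reverse": rev.q.pval,
        "uni_ea_ad": uni_ea.q.pval,
        "uni_iq_ad": uni_iq.q.pval,
    }
    return {
        "run": run,
        "ivw_intelligence_on_education_sd": fwd.ivw.beta,
        "ivw_intelligence_on_education_se": fwd.ivw.se,
        "ivw_education_on_intelligence_sd": rev.ivw.beta,
        "ivw_education_on_intelligence_sd_steiger_filtered": rev.ivw_steiger.beta,
        "ivw_education_on_intelligence_filtered_se": rev.ivw_steiger.se,
        "education_snps_steiger_flagged": rev.n_steiger_flagged,
        "education_snps_total": rev.ivw.n_snps,
        "education_snps_steiger_flagged_pct": 100.0 * rev.n_steiger_flagged / rev.ivw.n_snps,
        "intelligence_snps_steiger_flagged": fwd.n_steiger_flagged,
        "uni_education_ad_pct_lower_odds": uni_ea.odds.percent_change,
        "uni_intelligence_ad_pct_lower_odds": uni_iq.odds.percent_change,
        "uni_education_ad_or": uni_ea.odds.odds_ratio,
        "uni_intelligence_ad_or": uni_iq.odds.odds_ratio,
        "mvmr_education_ad_or": math.exp(mv_ea.beta),
        "mvmr_education_ad_log_or_se": mv_ea.se,
        "mvmr_intelligence_ad_pct_lower_odds": 100.0 * (1 - math.exp(mv_iq.beta)),
        "mvmr_intelligence_ad_log_or_se": mv_iq.se,
        "mvmr_n_snps": mv_ea.n_snps,
        "f_stat_education": _f_stat(uni_ea).F,
        "f_stat_intelligence": _f_stat(uni_iq).F,
        "heterogeneity_q_pvals": q_pvals,
    }
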