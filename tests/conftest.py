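import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrkit.harmonize import HarmonizedDataset
from mrkit.sumstats import SummaryStatsTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20200131)


def build_table(
    betas,
    ses,
    trait_name="exposure",
    trait_type="continuous",
    eafs=None,
    pvals=None,
    n=10_000.0,
    alleles=("A", "G"),
    chrom=None,
    pos=None,
    snp_ids=None,
):
    """Small valid summary-statistics table from parallel arrays."""
    k = len(betas)
    eafs = eafs if eafs is not None else [0.3] * k
    pvals = pvals if pvals is not None else [1e-8] * k
    df = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"rs{i + 1}" for i in range(k)],
            "chrom": chrom if chrom is not None else ["1"] * k,
            "pos": pos if pos is not None else [1_000_000 * (i + 1) for i in range(k)],
            "effect_allele": [alleles[0]] * k,
            "other_allele": [alleles[1]] * k,
            "eaf": eafs,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": [n] * k,
        }
    )
    return SummaryStatsTable(trait_name, trait_type, df)


def build_dataset(
    bx,
    by,
    sey,
    sex=None,
    eaf=None,
    n_exp=100_000.0,
    n_out=50_000.0,
    exposure="exposure",
    outcome="outcome",
    outcome_type="continuous",
):
    """HarmonizedDataset from parallel arrays (single exposure)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sey = np.asarray(sey, float)
    k = len(bx)
    sex = np.asarray(sex, float) if sex is not None else np.full(k, 0.01)
    eaf = np.asarray(eaf, float) if eaf is not None else np.full(k, 0.3)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "chrom": ["1"] * k,
            "pos": np.arange(1, k + 1) * 1_000_000,
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "beta_exposure": bx,
            "se_exposure": sex,
            "eaf_exposure": eaf,
            "beta_outcome": by,
            "se_outcome": sey,
            "eaf_outcome": eaf,
            "n_exposure": n_exp,
            "n_outcome": n_out,
            "flag": ["unchanged"] * k,
        }
    )
    return HarmonizedDataset(
        exposure_names=(exposure,),
        outcome_name=outcome,
        outcome_type=outcome_type,
        df=df,
        dropped=pd.DataFrame(columns=["snp_id", "flag"]),
    )


def build_mv_dataset(bx1, bx2, by, sey, outcome_type="binary"):
    """Two-exposure HarmonizedDataset from parallel arrays."""
    bx1 = np.asarray(bx1, float)
    k = len(bx1)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "chrom": ["1"] * k,
            "pos": np.arange(1, k + 1) * 1_000_000,
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "beta_exposure_1": bx1,
            "se_exposure_1": 0.01,
            "eaf_exposure_1": 0.3,
            "beta_exposure_2": np.asarray(bx2, float),
            "se_exposure_2": 0.01,
            "eaf_exposure_2": 0.3,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sey, float),
            "eaf_outcome": 0.3,
            "n_exposure_1": 100_000.0,
            "n_exposure_2": 100_000.0,
            "n_outcome": 50_000.0,
            "flag": ["unchanged"] * k,
        }
    )
    return HarmonizedDataset(
        exposure_names=("exposure_1", "exposure_2"),
        outcome_name="outcome",
        outcome_type=outcome_type,
        df=df,
        dropped=pd.DataFrame(columns=["snp_id", "flag"]),
    )
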