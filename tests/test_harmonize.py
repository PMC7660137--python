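"""Harmonization rules, overlap exclusion, clumping and the MVMR dataset."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import build_table
from mrkit.exceptions import HarmonizationError, LDMissingError, ValidationError
from mrkit.harmonize import (
    DEFAULT_EAF_BAND,
    LDInfo,
    build_mvmr_dataset,
    exclude_overlap,
    greedy_clump,
    harmonize_pair,
    is_palindromic,
)
from mrkit.sumstats import SummaryStatsTable

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
ALL_PAIRS = [(x, y) for x in "ACGT" for y in "ACGT" if x != y]


def _oracle(ea_e, oa_e, ea_o, oa_o, eaf_e, eaf_o, band=DEFAULT_EAF_BAND):
    """Independent rule evaluation for one allele configuration.

    Returns 'same' (outcome beta kept), 'flip' (sign and EAF flipped),
    'drop_pal' or 'drop_bad'.
    """
    if _COMP[ea_e] == oa_e:  # exposure pair palindromic
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return "drop_bad"
        if band[0] < eaf_e < band[1] or band[0] < eaf_o < band[1]:
            return "drop_pal"
        return "same" if (eaf_e < 0.5) == (eaf_o < 0.5) else "flip"
    if (ea_o, oa_o) == (ea_e, oa_e):
        return "same"
    if (ea_o, oa_o) == (oa_e, ea_e):
        return "flip"
    if (_COMP[ea_o], _COMP[oa_o]) == (ea_e, oa_e):
        return "same"
    if (_COMP[ea_o], _COMP[oa_o]) == (oa_e, ea_e):
        return "flip"
    return "drop_bad"


def _one_snp_tables(exp_alleles, out_alleles, eaf_e, eaf_o, beta_out=0.03):
    exp = build_table([0.05], [0.01], eafs=[eaf_e], alleles=exp_alleles)
    out = build_table([beta_out], [0.012], eafs=[eaf_o], alleles=out_alleles,
                      trait_name="outcome")
    return exp, out


def test_exhaustive_allele_configurations_match_rule_oracle():
    """Every ordered exposure × outcome allele pair, with EAF inside and
    outside the ambiguity band, resolves exactly as the independently coded
    rule table says — including conservation (retained + dropped = 1)."""
    beta_out = 0.03
    for exp_al, out_al in itertools.product(ALL_PAIRS, ALL_PAIRS):
        for eaf_e, eaf_o in [(0.3, 0.3), (0.3, 0.7), (0.5, 0.5), (0.7, 0.44)]:
            verdict = _oracle(*exp_al, *out_al, eaf_e, eaf_o)
            exp, out = _one_snp_tables(exp_al, out_al, eaf_e, eaf_o, beta_out)
            ds = harmonize_pair(exp, out)
            assert ds.n_snps + len(ds.dropped) == 1, (exp_al, out_al)
            if verdict in ("drop_pal", "drop_bad"):
                assert ds.n_snps == 0, (exp_al, out_al, eaf_e, eaf_o)
                flag = ds.dropped.iloc[0]["flag"]
                expected = "dropped_palindromic" if verdict == "drop_pal" else "dropped_incompatible"
                assert flag == expected, (exp_al, out_al, eaf_e, eaf_o)
            else:
                assert ds.n_snps == 1, (exp_al, out_al, eaf_e, eaf_o)
                row = ds.df.iloc[0]
                want_beta = beta_out if verdict == "same" else -beta_out
                want_eaf = eaf_o if verdict == "same" else 1 - eaf_o
                assert row["beta_outcome"] == pytest.approx(want_beta)
                assert row["eaf_outcome"] == pytest.approx(want_eaf)
                assert row["effect_allele"] == exp_al[0]


def test_swap_correction_is_involutive():
    """Applying the allele-swap correction twice returns the original beta
    and EAF: harmonizing against a swapped-representation outcome and then
    re-swapping the result is the identity."""
    exp, out = _one_snp_tables(("A", "G"), ("G", "A"), 0.3, 0.7)
    ds = harmonize_pair(exp, out)
    row = ds.df.iloc[0]
    assert row["flag"] == "allele_swapped"
    assert row["beta_outcome"] == pytest.approx(-0.03)
    assert row["eaf_outcome"] == pytest.approx(0.3)
    # second application of the same correction restores the input
    assert -row["beta_outcome"] == pytest.approx(0.03)
    assert 1 - row["eaf_outcome"] == pytest.approx(0.7)


def test_harmonized_result_invariant_to_outcome_representation(rng):
    """For non-palindromic SNPs the harmonized dataset is identical whether
    the outcome GWAS reports the same, swapped, or strand-flipped alleles."""
    k = 8
    betas = rng.normal(0, 0.05, k)
    exp = build_table(rng.normal(0, 0.05, k), [0.01] * k, alleles=("A", "G"))
    base = build_table(betas, [0.012] * k, trait_name="outcome", alleles=("A", "G"))
    swapped_df = base.df.copy()
    swapped_df["effect_allele"], swapped_df["other_allele"] = "G", "A"
    swapped_df["beta"] = -swapped_df["beta"]
    swapped_df["eaf"] = 1 - swapped_df["eaf"]
    flipped_df = base.df.copy()
    flipped_df["effect_allele"], flipped_df["other_allele"] = "T", "C"
    ref = harmonize_pair(exp, base).df
    for variant_df in (swapped_df, flipped_df):
        variant = SummaryStatsTable("outcome", "continuous", variant_df)
        got = harmonize_pair(exp, variant).df
        np.testing.assert_allclose(got["beta_outcome"], ref["beta_outcome"], atol=1e-15)
        np.testing.assert_allclose(got["eaf_outcome"], ref["eaf_outcome"], atol=1e-15)


def test_palindromic_missing_eaf_hard_error_under_infer_policy():
    exp = build_table([0.05], [0.01], eafs=[0.2], alleles=("A", "T"))
    out_df = build_table([0.03], [0.012], alleles=("A", "T"), trait_name="outcome").df
    out_df["eaf"] = np.nan
    out = SummaryStatsTable("outcome", "continuous", out_df)
    with pytest.raises(HarmonizationError, match="rs1"):
        harmonize_pair(exp, out, palindrome_policy="infer_by_eaf")


def test_snps_missing_from_outcome_counted():
    exp = build_table([0.05, 0.04, 0.03], [0.01] * 3)
    out = build_table([0.02], [0.01], trait_name="outcome")
    ds = harmonize_pair(exp, out)
    assert ds.n_snps == 1
    assert ds.n_missing_outcome == 2
    with pytest.raises(ValidationError):
        harmonize_pair(exp, build_table([0.1], [0.01], snp_ids=["rsX"],
                                        trait_name="outcome"))


# ---------------------------------------------------------------------------
# overlap exclusion


def test_exclude_overlap_disjoint_and_shared():
    a = build_table([0.1, 0.2], [0.01] * 2, snp_ids=["rs1", "rs2"])
    b = build_table([0.3, 0.4], [0.01] * 2, snp_ids=["rs3", "rs4"], trait_name="b")
    a2, b2, ov = exclude_overlap(a, b)
    assert ov == [] and len(a2) == 2 and len(b2) == 2

    b = build_table([0.3, 0.4], [0.01] * 2, snp_ids=["rs2", "rs4"], trait_name="b")
    a2, b2, ov = exclude_overlap(a, b)
    assert ov == ["rs2"]
    assert a2.snp_ids == {"rs1"} and b2.snp_ids == {"rs4"}


# ---------------------------------------------------------------------------
# clumping


def _brute_force_clump(df, ld_pairs, r2_thr, window):
    """Independent greedy reference: repeatedly take smallest (pval, chrom,
    pos), delete neighbours in LD."""
    rows = df.to_dict("records")
    kept = []
    while rows:
        rows.sort(key=lambda r: (r["pval"], r["chrom"], r["pos"]))
        lead = rows.pop(0)
        kept.append(lead["snp_id"])
        survivors = []
        for r in rows:
            close = (r["chrom"] == lead["chrom"]
                     and abs(r["pos"] - lead["pos"]) <= window)
            r2 = ld_pairs.get(frozenset((r["snp_id"], lead["snp_id"])), 0.0)
            if not (close and r2 >= r2_thr):
                survivors.append(r)
        rows = survivors
    return sorted(kept)


def test_clump_without_ld_is_identity_with_notice():
    tab = build_table([0.1, 0.2], [0.01] * 2)
    assert greedy_clump(tab, ld=None) is tab


def test_clump_keeps_most_significant_of_ld_pair():
    tab = build_table([0.1, 0.2], [0.01, 0.01], pvals=[1e-10, 1e-8],
                      pos=[1_000_000, 1_001_000])
    ld = LDInfo({frozenset(("rs1", "rs2")): 0.9})
    out = greedy_clump(tab, ld)
    assert list(out.df["snp_id"]) == ["rs1"]


def test_clump_window_rule_keeps_distant_ld_pair():
    tab = build_table([0.1, 0.2], [0.01, 0.01], pvals=[1e-10, 1e-8],
                      pos=[1_000_000, 21_000_000])
    ld = LDInfo({frozenset(("rs1", "rs2")): 0.9})
    out = greedy_clump(tab, ld, window_bp=10_000_000)
    assert len(out) == 2


def test_clump_matches_bruteforce_on_small_random_instances(rng):
    """Greedy clumping equals an independently coded greedy reference on
    random <= 5-SNP instances, and is invariant to input row order."""
    for trial in range(60):
        k = int(rng.integers(2, 6))
        pos = sorted(rng.integers(1, 30_000_000, size=k).tolist())
        pvals = 10.0 ** rng.uniform(-12, -2, size=k)
        ids = [f"rs{i + 1}" for i in range(k)]
        pairs = {}
        for i in range(k):
            for j in range(i + 1, k):
                pairs[frozenset((ids[i], ids[j]))] = float(rng.uniform(0, 1) < 0.4) * float(rng.uniform(0, 1))
        tab = build_table(rng.normal(0, 0.1, k), [0.01] * k, pvals=pvals,
                          pos=pos, snp_ids=ids)
        ld = LDInfo(pairs)
        got = sorted(greedy_clump(tab, ld, 0.01, 10_000_000).df["snp_id"])
        want = _brute_force_clump(tab.df, pairs, 0.01, 10_000_000)
        assert got == want
        # order invariance
        shuffled = tab.df.sample(frac=1, random_state=trial).reset_index(drop=True)
        tab2 = SummaryStatsTable("exposure", "continuous", shuffled)
        assert sorted(greedy_clump(tab2, ld, 0.01, 10_000_000).df["snp_id"]) == want


def test_clump_missing_ld_pair_in_window_is_hard_error():
    tab = build_table([0.1, 0.2], [0.01, 0.01], pos=[1_000_000, 1_001_000])
    with pytest.raises(LDMissingError):
        greedy_clump(tab, LDInfo({}))


def test_ldinfo_matrix_and_pairlist_agree():
    ids = ["rs1", "rs2", "rs3"]
    mat = pd.DataFrame(
        [[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]], columns=ids
    )
    ld_m = LDInfo.from_matrix(mat)
    ld_p = LDInfo.from_pairs(pd.DataFrame(
        {"snp_a": ["rs1", "rs2", "rs1"], "snp_b": ["rs2", "rs3", "rs3"],
         "r2": [0.5, 0.2, 0.0]}
    ))
    for a, b in [("rs1", "rs2"), ("rs2", "rs3"), ("rs1", "rs3"), ("rs2", "rs2")]:
        assert ld_m.r2(a, b) == pytest.approx(ld_p.r2(a, b))


def test_ldinfo_rejects_invalid_matrix():
    ids = ["rs1", "rs2"]
    with pytest.raises(ValidationError):
        LDInfo.from_matrix(pd.DataFrame([[1.0, 0.4], [0.6, 1.0]], columns=ids))
    with pytest.raises(ValidationError):
        LDInfo({frozenset(("rs1", "rs2")): 1.4})


# ---------------------------------------------------------------------------
# MVMR dataset assembly


def test_build_mvmr_union_deduplicates():
    """4-SNP union with one duplicate gives 3 unique harmonized rows, each
    carrying both exposures' betas."""
    e1 = build_table([0.1, 0.2], [0.01] * 2, snp_ids=["rs1", "rs2"])
    e2 = build_table([0.3, 0.4], [0.01] * 2, snp_ids=["rs2", "rs3"],
                     trait_name="exposure2")
    full1 = build_table([0.1, 0.2, 0.05], [0.01] * 3, snp_ids=["rs1", "rs2", "rs3"])
    full2 = build_table([0.02, 0.3, 0.4], [0.01] * 3, snp_ids=["rs1", "rs2", "rs3"],
                        trait_name="exposure2")
    out = build_table([0.01, 0.02, 0.03], [0.012] * 3,
                      snp_ids=["rs1", "rs2", "rs3"], trait_name="AD",
                      trait_type="binary")
    ds = build_mvmr_dataset(e1, e2, {"exposure": full1, "exposure2": full2}, out)
    assert ds.n_snps == 3
    assert set(ds.df["snp_id"]) == {"rs1", "rs2", "rs3"}
    assert ds.n_exposures == 2
    row = ds.df.set_index("snp_id").loc["rs2"]
    assert row["beta_exposure_1"] == pytest.approx(0.2)
    assert row["beta_exposure_2"] == pytest.approx(0.3)


def test_build_mvmr_drops_rows_missing_cross_association():
    e1 = build_table([0.1, 0.2], [0.01] * 2, snp_ids=["rs1", "rs2"])
    e2 = build_table([0.3], [0.01], snp_ids=["rs3"], trait_name="exposure2")
    full1 = build_table([0.1, 0.2, 0.05], [0.01] * 3, snp_ids=["rs1", "rs2", "rs3"])
    full2 = build_table([0.02, 0.3], [0.01] * 2, snp_ids=["rs1", "rs3"],
                        trait_name="exposure2")  # rs2 missing
    out = build_table([0.01, 0.02, 0.03], [0.012] * 3,
                      snp_ids=["rs1", "rs2", "rs3"], trait_name="AD",
                      trait_type="binary")
    ds = build_mvmr_dataset(e1, e2, {"exposure": full1, "exposure2": full2}, out)
    assert ds.n_snps == 2
    assert list(ds.dropped["flag"]) == ["missing_cross_exposure2"]


def test_is_palindromic():
    assert is_palindromic("A", "T") and is_palindromic("G", "C")
    assert not is_palindromic("A", "G")
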