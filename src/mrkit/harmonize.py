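"""Harmonization of exposure and outcome summary statistics.

Two-sample MR requires every SNP's exposure and outcome associations to be
expressed for the *same* effect allele. For each SNP shared between tables:

* alleles match as stated → copy unchanged;
* outcome alleles are swapped relative to the exposure → negate the outcome
  beta and replace the outcome EAF by ``1 − eaf`` (``allele_swapped``);
* alleles match only after complementing both (A↔T, C↔G) → a strand
  difference between the source GWAS; complement and proceed
  (``strand_flipped``), possibly combined with a swap;
* palindromic SNPs (A/T or C/G) cannot be resolved by allele strings at all.
  Under the default ``drop_ambiguous`` policy they are dropped whenever
  either trait's EAF falls inside the ambiguity band around 0.5 (default
  0.42–0.58) and otherwise aligned by EAF concordance; under ``infer_by_eaf``
  they are always aligned by EAF concordance and a missing EAF is a hard
  error naming the SNP;
* irreconcilable allele sets → dropped (``dropped_incompatible``).

Strand complementing is attempted only after direct and swapped matching
both fail, which avoids spurious complement matches (those can only occur
for palindromic pairs, which are handled separately).

The module also provides cross-GWAS overlap exclusion, greedy LD clumping
(smallest p first, r² ≥ threshold within a base-pair window removed, ties
broken by genomic coordinate) and construction of the two-exposure dataset
used for multivariable MR.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    HarmonizationError,
    LDMissingError,
    ValidationError,
)
from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Provenance flags for harmonized rows.
FLAG_UNCHANGED = "unchanged"
FLAG_SWAPPED = "allele_swapped"
FLAG_FLIPPED = "strand_flipped"
FLAG_FLIPPED_SWAPPED = "strand_flipped+allele_swapped"
DROP_PALINDROMIC = "dropped_palindromic"
DROP_INCOMPATIBLE = "dropped_incompatible"
DROP_MISSING_OUTCOME = "dropped_missing_outcome"

DEFAULT_EAF_BAND = (0.42, 0.58)


def complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs read identically on both strands."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclasses.dataclass
class HarmonizedDataset:
    """Per-SNP exposure and outcome effects aligned to a shared effect allele.

    ``df`` columns for one exposure: ``snp_id, effect_allele, other_allele,
    beta_exposure, se_exposure, eaf_exposure, eaf_outcome, beta_outcome,
    se_outcome, n_exposure, n_outcome, flag``. For two exposures the exposure
    columns carry suffixes ``_1`` and ``_2``.

    ``dropped`` records every shared SNP that did not survive (id + flag),
    so retained + dropped counts always reconcile with the input overlap.
    """

    exposure_names: tuple[str, ...]
    outcome_name: str
    outcome_type: str
    df: pd.DataFrame
    dropped: pd.DataFrame
    n_missing_outcome: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def exposure_betas(self) -> np.ndarray:
        """(n_snps, n_exposures) matrix of exposure effects."""
        if self.n_exposures == 1:
            return self.df[["beta_exposure"]].to_numpy()
        return self.df[["beta_exposure_1", "beta_exposure_2"]].to_numpy()

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedDataset":
        wanted = set(snp_ids)
        return dataclasses.replace(
            self,
            df=self.df[self.df["snp_id"].isin(wanted)].reset_index(drop=True),
            dropped=self.dropped.iloc[0:0],
            n_missing_outcome=0,
        )

    def counts(self) -> dict[str, int]:
        out = {"retained": self.n_snps, "missing_from_outcome": self.n_missing_outcome}
        for flag, sub in self.dropped.groupby("flag"):
            out[str(flag)] = len(sub)
        return out


def _align_row(
    ea_ref: str,
    oa_ref: str,
    ea: str,
    oa: str,
    beta: float,
    eaf: float,
    eaf_ref: float,
    palindrome_policy: str,
    band: tuple[float, float],
    snp_id: str,
) -> tuple[str, float, float]:
    """Align one association (ea/oa/beta/eaf) to the reference alleles.

    Returns ``(flag, beta, eaf)`` with a ``dropped_*`` flag when the row
    cannot be aligned. The palindrome branch uses the reference-trait EAF
    (``eaf_ref``) and this row's EAF for concordance.
    """
    if is_palindromic(ea_ref, oa_ref):
        if {ea, oa} != {ea_ref, oa_ref}:
            return DROP_INCOMPATIBLE, beta, eaf
        if palindrome_policy == "drop_ambiguous":
            for f in (eaf_ref, eaf):
                if f is None or np.isnan(f):
                    logger.info("palindromic SNP %s dropped: EAF missing", snp_id)
                    return DROP_PALINDROMIC, beta, eaf
                if band[0] < f < band[1]:
                    return DROP_PALINDROMIC, beta, eaf
        elif palindrome_policy == "infer_by_eaf":
            if any(f is None or np.isnan(f) for f in (eaf_ref, eaf)):
                raise HarmonizationError(
                    f"palindromic SNP {snp_id}: EAF required under infer_by_eaf but missing"
                )
        else:
            raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
        # Align by frequency concordance: discordant minor/major status means
        # the stated effect alleles refer to opposite alleles.
        if (eaf_ref < 0.5) == (eaf < 0.5):
            return FLAG_UNCHANGED, beta, eaf
        return FLAG_SWAPPED, -beta, 1.0 - eaf

    if (ea, oa) == (ea_ref, oa_ref):
        return FLAG_UNCHANGED, beta, eaf
    if (ea, oa) == (oa_ref, ea_ref):
        return FLAG_SWAPPED, -beta, _flip_eaf(eaf)
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ea_ref, oa_ref):
        return FLAG_FLIPPED, beta, eaf
    if (cea, coa) == (oa_ref, ea_ref):
        return FLAG_FLIPPED_SWAPPED, -beta, _flip_eaf(eaf)
    return DROP_INCOMPATIBLE, beta, eaf


def _flip_eaf(eaf: float) -> float:
    return eaf if eaf is None or np.isnan(eaf) else 1.0 - eaf


def harmonize_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_band: tuple[float, float] = DEFAULT_EAF_BAND,
) -> HarmonizedDataset:
    """Align ``outcome`` rows to the effect alleles of ``exposure``.

    SNPs absent from the outcome table are dropped and counted in
    ``n_missing_outcome``. Raises :class:`ValidationError` when the tables
    share no SNPs at all.
    """
    exp = exposure.df.set_index("snp_id", drop=False)
    out = outcome.df.set_index("snp_id", drop=False)
    shared = [s for s in exposure.df["snp_id"] if s in out.index]
    n_missing = len(exposure.df) - len(shared)
    if not shared:
        raise ValidationError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    kept_rows = []
    dropped = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        flag, beta_o, eaf_o = _align_row(
            e["effect_allele"], e["other_allele"],
            o["effect_allele"], o["other_allele"],
            o["beta"], o["eaf"], e["eaf"],
            palindrome_policy, eaf_ambiguity_band, snp,
        )
        if flag.startswith("dropped"):
            dropped.append((snp, flag))
            continue
        kept_rows.append(
            {
                "snp_id": snp,
                "chrom": e["chrom"],
                "pos": e["pos"],
                "effect_allele": e["effect_allele"],
                "other_allele": e["other_allele"],
                "beta_exposure": e["beta"],
                "se_exposure": e["se"],
                "eaf_exposure": e["eaf"],
                "beta_outcome": beta_o,
                "se_outcome": o["se"],
                "eaf_outcome": eaf_o,
                "n_exposure": e["n"],
                "n_outcome": o["n"],
                "flag": flag,
            }
        )
    df = pd.DataFrame(kept_rows)
    dropped_df = pd.DataFrame(dropped, columns=["snp_id", "flag"])
    logger.info(
        "harmonized %s -> %s: %d shared, %d retained, %d dropped, %d missing from outcome",
        exposure.trait_name, outcome.trait_name,
        len(shared), len(df), len(dropped_df), n_missing,
    )
    return HarmonizedDataset(
        exposure_names=(exposure.trait_name,),
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        df=df,
        dropped=dropped_df,
        n_missing_outcome=n_missing,
    )


def exclude_overlap(
    instruments_a: SummaryStatsTable, instruments_b: SummaryStatsTable
) -> tuple[SummaryStatsTable, SummaryStatsTable, list[str]]:
    """Remove SNPs present in both instrument lists from each list.

    Used for the bidirectional exposure↔exposure analysis, where a shared
    instrument cannot be assigned to either trait. Returns both reduced
    tables and the sorted overlap list (possibly empty).
    """
    overlap = sorted(instruments_a.snp_ids & instruments_b.snp_ids)
    if not overlap:
        return instruments_a, instruments_b, []
    keep_a = instruments_a.df[~instruments_a.df["snp_id"].isin(overlap)]
    keep_b = instruments_b.df[~instruments_b.df["snp_id"].isin(overlap)]
    a = SummaryStatsTable(instruments_a.trait_name, instruments_a.trait_type,
                          keep_a, instruments_a.trait_sd_label)
    b = SummaryStatsTable(instruments_b.trait_name, instruments_b.trait_type,
                          keep_b, instruments_b.trait_sd_label)
    return a, b, overlap


class LDInfo:
    """Pairwise r² between SNPs, from a pair list or a square matrix.

    ``r2(a, b)`` returns the stored value, 1.0 on the diagonal, and ``None``
    for unknown pairs (the clumping routine decides whether that is fatal).
    """

    def __init__(self, pairs: Mapping[frozenset, float], window_bp: int | None = None):
        for key, r2 in pairs.items():
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"r² out of [0, 1] for pair {sorted(key)}: {r2}")
        self._pairs = dict(pairs)
        self.window_bp = window_bp

    @classmethod
    def from_pairs(cls, frame: pd.DataFrame, window_bp: int | None = None) -> "LDInfo":
        """3-column pair list: snp_a, snp_b, r2 (symmetric by construction)."""
        cols = list(frame.columns[:3])
        pairs = {
            frozenset((str(a), str(b))): float(r)
            for a, b, r in frame[cols].itertuples(index=False)
            if str(a) != str(b)
        }
        return cls(pairs, window_bp)

    @classmethod
    def from_matrix(cls, frame: pd.DataFrame, window_bp: int | None = None) -> "LDInfo":
        """Square matrix with snp_ids as both header and index."""
        mat = frame.to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise ValidationError("LD matrix is not square")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        ids = [str(c) for c in frame.columns]
        pairs = {}
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                pairs[frozenset((a, ids[j]))] = float(mat[i, j])
        return cls(pairs, window_bp)

    @classmethod
    def read(cls, path, window_bp: int | None = None) -> "LDInfo":
        """Auto-detect pair-list (3 columns) vs matrix (header of snp_ids)."""
        frame = pd.read_csv(path, sep=None, engine="python")
        if frame.shape[1] == 3 and not np.issubdtype(frame.dtypes.iloc[0], np.number):
            return cls.from_pairs(frame, window_bp)
        return cls.from_matrix(frame.set_index(frame.columns[0]) if
                               frame.shape[0] + 1 == frame.shape[1] else frame, window_bp)

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)))


def greedy_clump(
    table: SummaryStatsTable,
    ld: LDInfo | None = None,
    r2_threshold: float = 0.01,
    window_bp: int = 10_000_000,
) -> SummaryStatsTable:
    """Greedy selection of approximately independent SNPs.

    Iteratively retain the smallest-p SNP and remove every SNP on the same
    chromosome within ``window_bp`` whose r² with it is at or above
    ``r2_threshold``. Ties on p are broken by (chrom, pos), making the result
    independent of input row order. Without LD information the table is
    treated as pre-clumped (published lead-SNP lists are approximately
    independent already) and returned unchanged, with a logged notice. A pair
    inside the window with no LD value is a hard error — independence is
    never silently assumed.
    """
    if ld is None:
        logger.info(
            "greedy_clump: no LD information for %s; table treated as pre-clumped",
            table.trait_name,
        )
        return table

    df = table.df
    order = df.sort_values(
        ["pval", "chrom", "pos"], kind="mergesort"
    ).index.tolist()
    alive = set(order)
    kept: list = []
    by_idx = df.to_dict("index")
    while order:
        lead = order.pop(0)
        if lead not in alive:
            continue
        kept.append(lead)
        alive.discard(lead)
        lead_row = by_idx[lead]
        for other in list(alive):
            row = by_idx[other]
            if row["chrom"] != lead_row["chrom"]:
                continue
            if abs(int(row["pos"]) - int(lead_row["pos"])) > window_bp:
                continue
            r2 = ld.r2(str(lead_row["snp_id"]), str(row["snp_id"]))
            if r2 is None:
                raise LDMissingError(
                    f"no r² for pair ({lead_row['snp_id']}, {row['snp_id']}) "
                    f"within {window_bp} bp window"
                )
            if r2 >= r2_threshold:
                alive.discard(other)
    kept_df = df.loc[sorted(kept)]  # original row order among survivors
    return SummaryStatsTable(table.trait_name, table.trait_type, kept_df,
                             table.trait_sd_label)


def build_mvmr_dataset(
    exposure1: SummaryStatsTable,
    exposure2: SummaryStatsTable,
    cross_assoc: Mapping[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDInfo | None = None,
    r2_threshold: float = 0.01,
    window_bp: int = 10_000_000,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_band: tuple[float, float] = DEFAULT_EAF_BAND,
) -> HarmonizedDataset:
    """Assemble the two-exposure dataset for multivariable MR.

    The union of both instrument lists is clumped, then each retained SNP is
    given its association with *both* exposures (looked up in ``cross_assoc``,
    keyed by trait name — full GWAS tables covering the other exposure's
    instruments) and with the outcome, all aligned to the instrument row's
    effect allele. Rows missing a cross association or outcome row are
    dropped and counted.
    """
    for name in (exposure1.trait_name, exposure2.trait_name):
        if name not in cross_assoc:
            raise ConfigurationError(
                f"cross_assoc must provide a lookup table for exposure {name!r}"
            )

    union = pd.concat([exposure1.df, exposure2.df], ignore_index=True)
    # One row per SNP; for duplicates keep the more significant discovery so
    # clump priority reflects the stronger association.
    union = union.sort_values(["pval", "chrom", "pos"], kind="mergesort")
    union = union.drop_duplicates("snp_id", keep="first")
    union_table = SummaryStatsTable(
        f"{exposure1.trait_name}+{exposure2.trait_name}", "continuous", union
    )
    clumped = greedy_clump(union_table, ld, r2_threshold, window_bp)

    lookups = {
        name: tab.df.set_index("snp_id", drop=False)
        for name, tab in cross_assoc.items()
    }
    out_lookup = outcome.df.set_index("snp_id", drop=False)

    rows = []
    dropped = []
    n_missing_outcome = 0
    for _, ref in clumped.df.iterrows():
        snp = ref["snp_id"]
        if snp not in out_lookup.index:
            n_missing_outcome += 1
            continue
        aligned = {}
        ok = True
        for k, name in enumerate((exposure1.trait_name, exposure2.trait_name), start=1):
            look = lookups[name]
            if snp not in look.index:
                dropped.append((snp, f"missing_cross_{name}"))
                ok = False
                break
            src = look.loc[snp]
            flag, beta, eaf = _align_row(
                ref["effect_allele"], ref["other_allele"],
                src["effect_allele"], src["other_allele"],
                src["beta"], src["eaf"], ref["eaf"],
                palindrome_policy, eaf_ambiguity_band, snp,
            )
            if flag.startswith("dropped"):
                dropped.append((snp, flag))
                ok = False
                break
            aligned[f"beta_exposure_{k}"] = beta
            aligned[f"se_exposure_{k}"] = src["se"]
            aligned[f"eaf_exposure_{k}"] = eaf
            aligned[f"n_exposure_{k}"] = src["n"]
        if not ok:
            continue
        o = out_lookup.loc[snp]
        flag, beta_o, eaf_o = _align_row(
            ref["effect_allele"], ref["other_allele"],
            o["effect_allele"], o["other_allele"],
            o["beta"], o["eaf"], ref["eaf"],
            palindrome_policy, eaf_ambiguity_band, snp,
        )
        if flag.startswith("dropped"):
            dropped.append((snp, flag))
            continue
        rows.append(
            {
                "snp_id": snp,
                "chrom": ref["chrom"],
                "pos": ref["pos"],
                "effect_allele": ref["effect_allele"],
                "other_allele": ref["other_allele"],
                **aligned,
                "beta_outcome": beta_o,
                "se_outcome": o["se"],
                "eaf_outcome": eaf_o,
                "n_outcome": o["n"],
                "flag": flag,
            }
        )
    if not rows:
        raise ValidationError("multivariable dataset is empty after harmonization")
    return HarmonizedDataset(
        exposure_names=(exposure1.trait_name, exposure2.trait_name),
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        df=pd.DataFrame(rows),
        dropped=pd.DataFrame(dropped, columns=["snp_id", "flag"]),
        n_missing_outcome=n_missing_outcome,
    )
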