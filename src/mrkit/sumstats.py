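"""Reading, validating and writing GWAS summary-statistic tables.

A summary-statistic table has one row per biallelic SNP with its identifier,
genomic coordinates (1-based positions), effect/other alleles, effect-allele
frequency (EAF), the per-allele association estimate (beta in SD units for
continuous traits, log odds ratio for binary traits), its standard error,
p-value and sample size.

Input files are delimited text (TSV or CSV, auto-detected unless configured)
with a user-supplied column map from the canonical field names to the file's
headers. Rows that violate the per-variant invariants are *rejected* — never
silently fixed — and every rejection is logged with its reason; table-level
problems (duplicate ids, empty tables, missing mapped columns) raise.

Numbers are parsed at full precision and written back with at least 12
significant digits, so read∘write is the identity on valid tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column names, in canonical order.
CANONICAL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

VALID_ALLELES = frozenset("ACGT")

#: Significant digits used when writing numeric fields (>= 10 required for
#: lossless round-trips at double precision for practical purposes).
FLOAT_FORMAT = "%.12g"


@dataclasses.dataclass
class VariantAssociation:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def invariant_violations(self) -> list[str]:
        """Return the list of invariant violations (empty if valid)."""
        reasons: list[str] = []
        ea = str(self.effect_allele).upper()
        oa = str(self.other_allele).upper()
        if ea not in VALID_ALLELES:
            reasons.append(f"effect_allele {self.effect_allele!r} is not a single base in ACGT")
        if oa not in VALID_ALLELES:
            reasons.append(f"other_allele {self.other_allele!r} is not a single base in ACGT")
        if ea in VALID_ALLELES and oa in VALID_ALLELES and ea == oa:
            reasons.append("effect_allele equals other_allele")
        if not (math.isfinite(self.beta)):
            reasons.append("beta is not finite")
        if not (self.se > 0):
            reasons.append(f"se must be > 0 (got {self.se})")
        if not (0 < self.pval <= 1):
            reasons.append(f"pval must be in (0, 1] (got {self.pval})")
        if self.eaf is not None and not math.isnan(self.eaf):
            if not (0 < self.eaf < 1):
                reasons.append(f"eaf must be in (0, 1) (got {self.eaf})")
        if self.n is not None and not math.isnan(self.n) and not (self.n > 0):
            reasons.append(f"n must be positive (got {self.n})")
        try:
            if int(self.pos) < 1:
                reasons.append(f"pos must be a positive 1-based coordinate (got {self.pos})")
        except (TypeError, ValueError):
            reasons.append(f"pos is not an integer (got {self.pos!r})")
        return reasons


class SummaryStatsTable:
    """A validated, ordered collection of :class:`VariantAssociation` rows.

    Parameters
    ----------
    trait_name :
        Name of the trait (e.g. ``"years_of_schooling"``).
    trait_type :
        ``"continuous"`` (betas in SD units) or ``"binary"`` (log odds ratios).
    df :
        DataFrame with the canonical columns. Validated on construction.
    trait_sd_label :
        Free-text description of one SD of the trait (e.g. ``"3.6 years"``).
    rejections :
        DataFrame of rejected input rows (``row``, ``snp_id``, ``reason``),
        populated by :func:`read_sumstats` / :meth:`from_dataframe`.
    """

    def __init__(
        self,
        trait_name: str,
        trait_type: str,
        df: pd.DataFrame,
        trait_sd_label: str = "",
        rejections: pd.DataFrame | None = None,
    ):
        if trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {trait_type!r}"
            )
        missing = [c for c in CANONICAL_FIELDS if c not in df.columns]
        if missing:
            raise ValidationError(f"table for {trait_name!r} lacks columns {missing}")
        if len(df) == 0:
            raise ValidationError(f"summary-statistics table for {trait_name!r} is empty")
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate snp_id in table for {trait_name!r}: {sorted(set(dup))}"
            )
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.trait_sd_label = trait_sd_label
        df = df.reset_index(drop=True)
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()
        self.df = df
        self.rejections = (
            rejections
            if rejections is not None
            else pd.DataFrame(columns=["row", "snp_id", "reason"])
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait_name: str,
        trait_type: str,
        trait_sd_label: str = "",
    ) -> "SummaryStatsTable":
        """Validate a raw DataFrame row by row, rejecting invalid rows.

        Row order is preserved; alleles are upper-cased. Output row count plus
        rejection count equals the input row count.
        """
        keep_rows: list[int] = []
        rejections: list[tuple[int, str, str]] = []
        records = df.to_dict("records")
        for i, rec in enumerate(records):
            va = _record_to_variant(rec)
            reasons = va.invariant_violations()
            if reasons:
                rejections.append((i, str(rec.get("snp_id", "?")), "; ".join(reasons)))
                logger.info(
                    "rejected row %d (snp %s) of %s: %s",
                    i, rec.get("snp_id", "?"), trait_name, "; ".join(reasons),
                )
            else:
                keep_rows.append(i)
        clean = df.iloc[keep_rows].copy()
        if len(clean) == 0:
            raise ValidationError(
                f"no valid rows remain for {trait_name!r} "
                f"({len(rejections)} of {len(df)} rows rejected)"
            )
        clean["effect_allele"] = clean["effect_allele"].astype(str).str.upper()
        clean["other_allele"] = clean["other_allele"].astype(str).str.upper()
        clean["snp_id"] = clean["snp_id"].astype(str)
        clean["chrom"] = clean["chrom"].astype(str)
        clean["pos"] = clean["pos"].astype(np.int64)
        for col in ("eaf", "beta", "se", "pval", "n"):
            clean[col] = pd.to_numeric(clean[col], errors="coerce").astype(float)
        rej = pd.DataFrame(rejections, columns=["row", "snp_id", "reason"])
        return cls(trait_name, trait_type, clean[list(CANONICAL_FIELDS) + _extra_cols(clean)],
                   trait_sd_label, rej)

    @classmethod
    def from_records(
        cls,
        records: Sequence[VariantAssociation],
        trait_name: str,
        trait_type: str,
        trait_sd_label: str = "",
    ) -> "SummaryStatsTable":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        return cls.from_dataframe(df, trait_name, trait_type, trait_sd_label)

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> set[str]:
        return set(self.df["snp_id"])

    def get(self, snp_id: str) -> pd.Series:
        hit = self.df[self.df["snp_id"] == snp_id]
        if len(hit) == 0:
            raise KeyError(snp_id)
        return hit.iloc[0]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatsTable":
        """Rows for the given ids, in this table's order. Rejections not carried."""
        wanted = set(snp_ids)
        sub = self.df[self.df["snp_id"].isin(wanted)].copy()
        return SummaryStatsTable(self.trait_name, self.trait_type, sub, self.trait_sd_label)

    def records(self) -> list[VariantAssociation]:
        return [_record_to_variant(rec) for rec in self.df[list(CANONICAL_FIELDS)].to_dict("records")]


def _extra_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in CANONICAL_FIELDS]


def _record_to_variant(rec: Mapping) -> VariantAssociation:
    def _f(key, default=None):
        v = rec.get(key, default)
        if v is None:
            return None
        try:
            return float(v)
        except (TypeError, ValueError):
            return math.nan

    return VariantAssociation(
        snp_id=str(rec.get("snp_id", "")),
        chrom=str(rec.get("chrom", "")),
        pos=rec.get("pos", -1),
        effect_allele=str(rec.get("effect_allele", "")).upper(),
        other_allele=str(rec.get("other_allele", "")).upper(),
        eaf=_f("eaf"),
        beta=_f("beta", math.nan),
        se=_f("se", math.nan),
        pval=_f("pval", math.nan),
        n=_f("n"),
    )


# ---------------------------------------------------------------------------
# File IO


def read_sumstats(
    path: str | Path,
    trait_name: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    trait_sd_label: str = "",
    delimiter: str | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    ``column_map`` maps canonical field names (see :data:`CANONICAL_FIELDS`)
    to the source file's column names; canonical names are assumed for any
    field not mapped. The delimiter is auto-detected (tab or comma) unless
    given. Missing mapped columns raise :class:`ConfigurationError`; invalid
    rows are rejected and logged (see ``.rejections`` on the result).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=delimiter, dtype={"snp_id": str, "chrom": str})
    column_map = dict(column_map or {})
    rename = {}
    missing = []
    for canon in CANONICAL_FIELDS:
        source = column_map.get(canon, canon)
        if source in raw.columns:
            rename[source] = canon
        elif canon in ("eaf", "n"):  # optional on read; operations fail loudly later
            raw[canon] = math.nan
        else:
            missing.append(f"{canon} (looked for column {source!r})")
    if missing:
        raise ConfigurationError(
            f"{path}: missing mapped columns: {', '.join(missing)}"
        )
    raw = raw.rename(columns=rename)
    return SummaryStatsTable.from_dataframe(raw, trait_name, trait_type, trait_sd_label)


def write_sumstats(table: SummaryStatsTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a table with canonical headers at full stored precision."""
    table.df[list(CANONICAL_FIELDS)].to_csv(
        path, sep=delimiter, index=False, float_format=FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Results reporting

#: Column order of results tables written by :func:`write_report`.
REPORT_COLUMNS = (
    "method",
    "exposure",
    "outcome",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "weights_model",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
)


def _result_to_row(res) -> dict:
    """Flatten an MREstimate / EggerResult / plain mapping into a report row."""
    # Imported lazily to avoid an import cycle with mr_estimators.
    from .mr_estimators import EggerResult, MREstimate

    if isinstance(res, EggerResult):
        row = _result_to_row(res.slope)
        row["egger_intercept"] = res.intercept
        row["egger_intercept_se"] = res.intercept_se
        row["egger_intercept_pval"] = res.intercept_pval
        return row
    if isinstance(res, MREstimate):
        exposure = res.exposure
        if not isinstance(exposure, str):
            exposure = "+".join(exposure)
        row = {
            "method": res.method,
            "exposure": exposure,
            "outcome": res.outcome,
            "n_snps": res.n_snps,
            "beta": res.beta,
            "se": res.se,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "pval": res.pval,
            "weights_model": res.weights_model,
        }
        if res.outcome_type == "binary":
            row["odds_ratio"] = math.exp(res.beta)
            row["or_ci_low"] = math.exp(res.ci_low)
            row["or_ci_high"] = math.exp(res.ci_high)
        return row
    if isinstance(res, Mapping):
        return dict(res)
    raise TypeError(f"cannot report a result of type {type(res).__name__}")


def write_report(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write a delimited results table; returns the frame written.

    ``results`` is a non-empty sequence of :class:`~mrkit.mr_estimators.MREstimate`,
    :class:`~mrkit.mr_estimators.EggerResult` or plain mappings. Odds-scale
    columns are filled only for binary outcomes.
    """
    if not results:
        raise ValidationError("write_report called with no results")
    rows = [_result_to_row(r) for r in results]
    frame = pd.DataFrame(rows)
    ordered = [c for c in REPORT_COLUMNS if c in frame.columns]
    ordered += [c for c in frame.columns if c not in ordered]
    frame = frame[ordered]
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return frame


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, config: Mapping, seed: int | None = None) -> None:
    """Write a machine-readable run manifest (config, seed, versions)."""
    import scipy
    import statsmodels

    from . import __version__

    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "mrkit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
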