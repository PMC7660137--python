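"""Study orchestration: bidirectional exposure↔exposure MR, univariable
exposure→outcome MR, multivariable MR, and the sensitivity suite, from
summary-statistic tables or from a simulated scenario.

Two deliberately different overlap policies are pinned per analysis type:

* the **bidirectional** exposure↔exposure analysis excludes instruments
  shared between the two GWAS (a shared hit cannot be assigned a
  direction), then Steiger-filters each direction and re-estimates;
* the **univariable exposure→outcome** analyses retain shared instruments —
  that is exactly how a typical univariable analysis would be run, and the
  contrast with the multivariable model is the point.

Every stage records SNP counts in and out (harmonization flags, overlap
exclusion, clumping, Steiger), so instrument attrition is fully auditable.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diagnostics as dx
from .exceptions import ConfigurationError, MRKitError
from .harmonize import (
    HarmonizedDataset,
    LDInfo,
    build_mvmr_dataset,
    exclude_overlap,
    harmonize_pair,
)
from .mr_estimators import (
    EggerResult,
    MREstimate,
    OddsScaleSummary,
    egger,
    ivw,
    mvmr_ivw,
    to_odds_scale,
)
from .sumstats import (
    SummaryStatsTable,
    read_sumstats,
    write_manifest,
    write_report,
    write_sumstats,
)
from .synthetic_gwas import AD, EA, IQ, ScenarioConfig, TwoSampleStudy, make_two_sample_study

logger = logging.getLogger(__name__)


@contextlib.contextmanager
def _stage(name: str):
    """Tag any analysis error with the pipeline stage it arose in."""
    try:
        yield
    except MRKitError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


@dataclasses.dataclass
class UnivariableResult:
    """One exposure→outcome analysis with its sensitivity diagnostics."""

    exposure: str
    outcome: str
    dataset: HarmonizedDataset
    ivw: MREstimate
    egger: EggerResult | None = None
    q: dx.QResult | None = None
    loo: dx.LeaveOneOutResult | None = None
    funnel: dx.FunnelResult | None = None
    steiger_records: list[dx.SteigerRecord] | None = None
    ivw_steiger: MREstimate | None = None
    odds: OddsScaleSummary | None = None
    attrition: dict = dataclasses.field(default_factory=dict)

    @property
    def n_steiger_flagged(self) -> int | None:
        if self.steiger_records is None:
            return None
        return sum(1 for r in self.steiger_records if not r.direction_ok)


@dataclasses.dataclass
class BidirectionalReport:
    forward: UnivariableResult  # exposure B -> exposure A
    reverse: UnivariableResult  # exposure A -> exposure B
    overlap: list[str]


@dataclasses.dataclass
class ADReport:
    uni: dict[str, UnivariableResult]  # per exposure
    mvmr: tuple[MREstimate, MREstimate]
    mvmr_odds: tuple[OddsScaleSummary, OddsScaleSummary]
    mvmr_dataset: HarmonizedDataset
    attrition: dict


def _analyze_univariable(
    exposure: SummaryStatsTable,
    outcome_table: SummaryStatsTable,
    weights_model: str,
    sensitivity: bool,
    steiger: bool = False,
    r2_method: str = "eaf_beta",
    palindrome_policy: str = "drop_ambiguous",
) -> UnivariableResult:
    with _stage(f"harmonize {exposure.trait_name}->{outcome_table.trait_name}"):
        ds = harmonize_pair(exposure, outcome_table, palindrome_policy)
    attrition = {"instruments_in": len(exposure), **ds.counts()}
    with _stage(f"ivw {exposure.trait_name}->{outcome_table.trait_name}"):
        est = ivw(ds, weights_model)
    res = UnivariableResult(
        exposure=exposure.trait_name,
        outcome=outcome_table.trait_name,
        dataset=ds,
        ivw=est,
        attrition=attrition,
    )
    if sensitivity:
        with _stage("sensitivity"):
            if ds.n_snps >= 3:
                res.egger = egger(ds)
                res.loo = dx.leave_one_out(ds, weights_model)
            if ds.n_snps >= 2:
                res.q = dx.cochrans_q(ds)
            res.funnel = dx.funnel_data(ds)
    if steiger:
        with _stage("steiger"):
            res.steiger_records, filtered = dx.steiger_filter(ds, r2_method)
            attrition["steiger_retained"] = filtered.n_snps
            if filtered.n_snps >= 1:
                res.ivw_steiger = ivw(filtered, weights_model)
    if outcome_table.trait_type == "binary":
        res.odds = to_odds_scale(est)
    return res


def run_bidirectional(
    instruments_a: SummaryStatsTable,
    instruments_b: SummaryStatsTable,
    outcome_table_a: SummaryStatsTable,
    outcome_table_b: SummaryStatsTable,
    weights_model: str = "multiplicative_random",
    r2_method: str = "eaf_beta",
    sensitivity: bool = True,
) -> BidirectionalReport:
    """Total effects of exposure B on exposure A and vice versa.

    ``outcome_table_a`` holds associations with trait A (for the B→A
    direction) and must cover B's instruments; correspondingly for
    ``outcome_table_b``. Overlapping instruments are excluded, both
    directions are estimated by IVW, then Steiger-filtered and
    re-estimated.
    """
    with _stage("overlap exclusion"):
        kept_a, kept_b, overlap = exclude_overlap(instruments_a, instruments_b)
    forward = _analyze_univariable(
        kept_b, outcome_table_a, weights_model, sensitivity,
        steiger=True, r2_method=r2_method,
    )
    reverse = _analyze_univariable(
        kept_a, outcome_table_b, weights_model, sensitivity,
        steiger=True, r2_method=r2_method,
    )
    for res in (forward, reverse):
        res.attrition["overlap_excluded"] = len(overlap)
    return BidirectionalReport(forward=forward, reverse=reverse, overlap=overlap)


def run_ad_analysis(
    instruments_a: SummaryStatsTable,
    instruments_b: SummaryStatsTable,
    full_a: SummaryStatsTable,
    full_b: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDInfo | None = None,
    weights_model: str = "multiplicative_random",
    sensitivity: bool = True,
) -> ADReport:
    """Univariable total effects of each exposure on the (binary) outcome,
    plus the multivariable model giving each exposure's direct effect.

    Overlapping instruments are *retained* in the univariable analyses.
    The multivariable dataset is the clumped union of both panels with each
    SNP's association with both exposures (``full_a``/``full_b`` are the
    lookup tables) harmonized to the outcome.
    """
    uni = {}
    for instr in (instruments_a, instruments_b):
        uni[instr.trait_name] = _analyze_univariable(
            instr, outcome, weights_model, sensitivity
        )
    with _stage("mvmr dataset"):
        mv_ds = build_mvmr_dataset(
            instruments_a, instruments_b,
            {full_a.trait_name: full_a, full_b.trait_name: full_b},
            outcome, ld,
        )
    with _stage("mvmr"):
        est_a, est_b = mvmr_ivw(mv_ds, weights_model)
    attrition = {
        "panel_a": len(instruments_a),
        "panel_b": len(instruments_b),
        "union_overlap": len(instruments_a.snp_ids & instruments_b.snp_ids),
        **{f"mvmr_{k}": v for k, v in mv_ds.counts().items()},
    }
    return ADReport(
        uni=uni,
        mvmr=(est_a, est_b),
        mvmr_odds=(to_odds_scale(est_a), to_odds_scale(est_b)),
        mvmr_dataset=mv_ds,
        attrition=attrition,
    )


@dataclasses.dataclass
class StudyRun:
    """Everything the full study produces for one pair of exposures + AD."""

    bidirectional: BidirectionalReport
    ad: ADReport
    study: TwoSampleStudy | None = None


def run_simulated_study(
    config: ScenarioConfig,
    weights_model: str = "multiplicative_random",
    sensitivity: bool = True,
) -> StudyRun:
    """Simulate a scenario and run the complete analysis suite on it."""
    with _stage("simulate"):
        study = make_two_sample_study(config)
    bidir = run_bidirectional(
        study.instruments(EA), study.instruments(IQ),
        study.outcome_tables[EA], study.outcome_tables[IQ],
        weights_model, sensitivity=sensitivity,
    )
    ad = run_ad_analysis(
        study.instruments(EA), study.instruments(IQ),
        study.exposure_tables[EA], study.exposure_tables[IQ],
        study.outcome_tables[AD],
        weights_model=weights_model, sensitivity=sensitivity,
    )
    return StudyRun(bidirectional=bidir, ad=ad, study=study)


# ---------------------------------------------------------------------------
# Run directory layout


def _all_estimates(run: StudyRun) -> list:
    out = []
    for direction, res in (("forward", run.bidirectional.forward),
                           ("reverse", run.bidirectional.reverse)):
        out.append(res.ivw)
        if res.ivw_steiger is not None:
            est = dataclasses.replace(res.ivw_steiger, method=res.ivw_steiger.method + "_steiger")
            out.append(est)
        if res.egger is not None:
            out.append(res.egger)
    for res in run.ad.uni.values():
        out.append(res.ivw)
        if res.egger is not None:
            out.append(res.egger)
    out.extend(run.ad.mvmr)
    return out


def write_run(outdir: str | Path, run: StudyRun, config: Mapping, seed: int | None) -> Path:
    """Write the deterministic run layout: tables/, diagnostics/,
    manifest.json, log.txt."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "diagnostics").mkdir(parents=True, exist_ok=True)

    write_report(_all_estimates(run), outdir / "tables" / "estimates.tsv")

    attrition_rows = []
    named = {
        "bidirectional_forward": run.bidirectional.forward,
        "bidirectional_reverse": run.bidirectional.reverse,
        **{f"univariable_{k}": v for k, v in run.ad.uni.items()},
    }
    for name, res in named.items():
        for key, val in res.attrition.items():
            attrition_rows.append({"analysis": name, "stage": key, "n": val})
    for key, val in run.ad.attrition.items():
        attrition_rows.append({"analysis": "mvmr", "stage": key, "n": val})
    pd.DataFrame(attrition_rows).to_csv(outdir / "tables" / "attrition.tsv",
                                        sep="\t", index=False)

    for name, res in named.items():
        if res.steiger_records is not None:
            dx.steiger_records_frame(res.steiger_records).to_csv(
                outdir / "diagnostics" / f"steiger_{name}.tsv", sep="\t", index=False
            )
        if res.loo is not None:
            res.loo.to_frame().to_csv(
                outdir / "diagnostics" / f"loo_{name}.tsv", sep="\t", index=False
            )
        if res.funnel is not None:
            res.funnel.table.to_csv(
                outdir / "diagnostics" / f"funnel_{name}.tsv", sep="\t", index=False
            )
    q_rows = [
        {"analysis": name, "Q": res.q.Q, "df": res.q.df, "pval": res.q.pval}
        for name, res in named.items()
        if res.q is not None
    ]
    if q_rows:
        pd.DataFrame(q_rows).to_csv(outdir / "diagnostics" / "q_stats.tsv",
                                    sep="\t", index=False)

    write_manifest(outdir / "manifest.json", config, seed)
    with open(outdir / "log.txt", "w") as fh:
        fh.write("stages completed: simulate/load, harmonize, estimate, sensitivity\n")
        for row in attrition_rows:
            fh.write(f"{row['analysis']}\t{row['stage']}\t{row['n']}\n")
    return outdir


def render_report_text(run_dir: str | Path) -> str:
    """Regenerate the human-readable summary from a run directory without
    recomputation (reads the stored tables only)."""
    run_dir = Path(run_dir)
    est_path = run_dir / "tables" / "estimates.tsv"
    if not est_path.exists():
        raise ConfigurationError(f"not a run directory (no {est_path})")
    est = pd.read_csv(est_path, sep="\t")
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [
        "MR analysis report",
        "==================",
        f"seed: {manifest.get('seed')}",
        "",
    ]
    for _, row in est.iterrows():
        ci = f"({row['ci_low']:.3f}, {row['ci_high']:.3f})"
        line = (
            f"{row['method']:<18} {row['exposure']} -> {row['outcome']}: "
            f"beta = {row['beta']:.3f} {ci}, p = {row['pval']:.3g}, "
            f"n_snps = {row['n_snps']}"
        )
        if "odds_ratio" in est.columns and pd.notna(row.get("odds_ratio")):
            line += f", OR = {row['odds_ratio']:.3f}"
        lines.append(line)
    att_path = run_dir / "tables" / "attrition.tsv"
    if att_path.exists():
        att = pd.read_csv(att_path, sep="\t")
        lines += ["", "Instrument attrition", "--------------------"]
        for _, row in att.iterrows():
            lines.append(f"{row['analysis']:<24} {row['stage']:<28} {row['n']}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Config-driven entry (real data or scenario)


_TOP_KEYS = {"scenario", "data", "settings", "out", "seed", "analyses"}
_DATA_KEYS = {"exposure_a", "exposure_b", "outcome", "ld"}
_TABLE_KEYS = {"instruments", "full", "path", "column_map", "trait_name",
               "trait_type", "trait_sd_label"}
_SETTINGS_KEYS = {"weights_model", "palindrome_policy", "r2_method",
                  "sensitivity", "r2_threshold", "window_bp"}


def load_analysis_config(path: str | Path) -> dict:
    """Load and schema-check a YAML analysis config.

    Exactly one of ``scenario`` (simulated run) or ``data`` (paths + column
    maps for real tables) must be present; unknown keys are reported.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    bad = sorted(set(raw) - _TOP_KEYS)
    if bad:
        raise ConfigurationError(f"unknown config keys: {bad}")
    has_scenario = "scenario" in raw
    has_data = "data" in raw
    if has_scenario == has_data:
        raise ConfigurationError("config must contain exactly one of 'scenario' or 'data'")
    if has_data:
        bad = sorted(set(raw["data"]) - _DATA_KEYS)
        if bad:
            raise ConfigurationError(f"unknown data keys: {bad}")
        for role in ("exposure_a", "exposure_b", "outcome"):
            if role not in raw["data"]:
                raise ConfigurationError(f"data section missing {role!r}")
            bad = sorted(set(raw["data"][role]) - _TABLE_KEYS)
            if bad:
                raise ConfigurationError(f"unknown keys under data.{role}: {bad}")
    bad = sorted(set(raw.get("settings", {}) or {}) - _SETTINGS_KEYS)
    if bad:
        raise ConfigurationError(f"unknown settings keys: {bad}")
    return raw


def _load_table(entry: Mapping, default_type: str, which: str) -> SummaryStatsTable:
    path = entry.get(which if which in entry else "path")
    if path is None or not Path(path).exists():
        raise ConfigurationError(f"input table not found: {path}")
    return read_sumstats(
        path,
        trait_name=entry.get("trait_name", Path(path).stem),
        trait_type=entry.get("trait_type", default_type),
        column_map=entry.get("column_map"),
        trait_sd_label=entry.get("trait_sd_label", ""),
    )


def run_from_config(config: Mapping, out: str | Path, seed: int | None = None) -> StudyRun:
    """Execute a full study from a parsed analysis config and write the run
    directory."""
    settings = dict(config.get("settings") or {})
    weights = settings.get("weights_model", "multiplicative_random")
    sensitivity = bool(settings.get("sensitivity", True))
    if "scenario" in config:
        scen = ScenarioConfig.from_mapping(config["scenario"])
        if seed is not None:
            scen = dataclasses.replace(scen, seed=seed)
        run = run_simulated_study(scen, weights, sensitivity)
        write_run(out, run, {"scenario": scen.to_dict(), "settings": settings}, scen.seed)
        return run

    data = config["data"]
    with _stage("load inputs"):
        instr_a = _load_table(data["exposure_a"], "continuous", "instruments")
        instr_b = _load_table(data["exposure_b"], "continuous", "instruments")
        full_a = _load_table(data["exposure_a"], "continuous", "full")
        full_b = _load_table(data["exposure_b"], "continuous", "full")
        outcome = _load_table(data["outcome"], "binary", "path")
        ld = LDInfo.read(data["ld"]) if data.get("ld") else None
    bidir = run_bidirectional(instr_a, instr_b, full_a, full_b, weights,
                              sensitivity=sensitivity)
    ad = run_ad_analysis(instr_a, instr_b, full_a, full_b, outcome, ld,
                         weights, sensitivity)
    run = StudyRun(bidirectional=bidir, ad=ad)
    write_run(out, run, dict(config), seed)
    return run


def write_study_tables(study: TwoSampleStudy, outdir: str | Path) -> Path:
    """Write a simulated study's summary-statistic tables, panels and
    ground truth to a directory (the ``mr simulate`` output)."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    for sample, tabs in (("exposure_sample", study.exposure_tables),
                         ("outcome_sample", study.outcome_tables)):
        for trait, tab in tabs.items():
            write_sumstats(tab, outdir / "tables" / f"{sample}_{trait}.tsv")
    truth = study.truth
    ground = {
        "total_iq_on_ea": truth.total_iq_on_ea,
        "total_ea_on_iq": truth.total_ea_on_iq,
        "total_ea_on_ad": truth.total_ea_on_ad,
        "total_iq_on_ad": truth.total_iq_on_ad,
        "mvmr_direct_ea": truth.mvmr_direct[0],
        "mvmr_direct_iq": truth.mvmr_direct[1],
        "iq_rescale_factor": truth.s,
        "panels": study.panels,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_manifest(outdir / "manifest.json", {"scenario": study.config.to_dict()},
                   study.config.seed)
    return outdir
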