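"""Synthetic GWAS summary statistics under known causal structures.

The generator realizes the catalogue of causal diagrams relating two
correlated continuous exposures — educational attainment (EA) and
intelligence (IQ), both in SD units — and a binary late-life outcome (AD)
on the log-odds scale: confounding of one exposure's association by the
other, full mediation, horizontal pleiotropy through either exposure,
genetically driven but causally disconnected traits, and joint effects with
a reciprocal EA↔IQ relationship.

Model
-----
Genotypes are independent biallelic SNPs, ``g_j ~ Binomial(2, maf_j)``.
Exposures are linear structural equations with standard-normal residuals
scaled so each exposure has **unit marginal variance**, keeping all path
coefficients in SD units:

* ``IQ₁ = Σ b_j g_j + c_iq·U + e_iq``  (the pre-feedback IQ),
* ``EA  = t_ie·IQ₁ + Σ a_j g_j + c_ea·U + e_ea``,
* ``IQ  = (IQ₁ + t_ei·(EA − t_ie·IQ₁)) / s`` — the reciprocal EA→IQ arrow is
  realized as a second assignment step feeding back only the non-IQ part of
  EA (a simultaneous loop would need an equilibrium convention), and ``s``
  restores unit variance,
* ``logit P(AD) = α + θ_ea·EA + θ_iq·IQ + Σ γ_j g_j + c_ad·U``,

where ``U`` is a shared standard-normal confounder and ``γ_j`` are direct
(horizontally pleiotropic) SNP effects. The user-facing trait↔trait
coefficients ``theta_iq_ea`` and ``theta_ea_iq`` are specified on the
*realized* per-SD scale; the internal coefficients ``t_ie = theta_iq_ea/s``
and ``t_ei = theta_ea_iq·s`` and the scale ``s`` have a closed form
(a quadratic in ``s``), so the ground-truth implied effects equal the
configured coefficients exactly. A variance budget exceeding 1 for either
exposure is a configuration error listing the contributions.

Two-sample estimation draws disjoint samples from the same generative law:
exposure associations come from sample 1, outcome associations from sample
2 (each trait's per-SNP regression is simple OLS for continuous traits and
univariate logistic regression for the binary outcome). Instruments are
selected in sample 1 at a p-value threshold, or taken as the designed panel
lists ("oracle" selection, emulating published lead-SNP tables).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit, logit

from .exceptions import ConfigurationError, MRKitError
from .sumstats import SummaryStatsTable

#: Non-palindromic (effect, other) allele pairs; palindromic A/T and C/G
#: pairs are excluded by default, emulating the standard practice of
#: avoiding strand-ambiguous variants when building instrument lists.
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

EA, IQ, AD = "education", "intelligence", "AD"


@dataclasses.dataclass
class ScenarioConfig:
    """Parameters of one causal structure for simulation.

    ``n_snps_ea`` / ``n_snps_iq`` are the sizes of the EA-specific and
    IQ-specific direct-effect SNP groups; ``ea_panel_from_iq`` additionally
    places that many IQ-acting SNPs on the EA instrument panel (of which
    ``panel_overlap`` are shared with the IQ panel), realizing
    direction-contaminated instrument lists. ``h2_ea`` / ``h2_iq`` are the
    total variances explained by each group's direct effects. Trait↔trait
    and trait→AD coefficients are per SD; ``pleiotropy_mean/sd`` parameterize
    direct SNP→AD log-odds effects; ``cross_*`` fields give SNPs effects on
    the other exposure (loading · own effect + independent noise).
    """

    scenario_id: str = "custom"
    n_snps_ea: int = 50
    n_snps_iq: int = 50
    ea_panel_from_iq: int = 0
    iq_panel_from_ea: int = 0
    panel_overlap: int = 0
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2_ea: float = 0.15
    h2_iq: float = 0.15
    theta_ea_iq: float = 0.0  # realized EA -> IQ effect, SD/SD
    theta_iq_ea: float = 0.0  # realized IQ -> EA effect, SD/SD
    theta_ea_ad: float = 0.0  # direct EA -> AD, log-odds per SD
    theta_iq_ad: float = 0.0  # direct IQ -> AD, log-odds per SD
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    iq_cross_loading: float = 0.0  # EA-group SNP effect on IQ = loading·a + noise
    ea_cross_loading: float = 0.0  # IQ-group SNP effect on EA = loading·b + noise
    cross_noise_sd: float = 0.0
    effect_distribution: str = "normal"  # or "fixed_magnitude" (equal per-SNP r²)
    confounder_strength: tuple[float, float, float] = (0.2, 0.2, 0.2)  # (EA, IQ, AD)
    n_sample_exposure: int = 20_000
    n_sample_outcome: int = 20_000
    ad_base_prevalence: float = 0.3
    selection: str = "pvalue"  # or "oracle" (designed panels)
    p_threshold: float = 1e-4  # desk-scale stand-in for genome-wide 5e-8
    seed: int = 20200131

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must be within (0, 0.5]: {self.maf_range}")
        if not (0 < self.ad_base_prevalence < 1):
            raise ConfigurationError(
                f"ad_base_prevalence must be in (0, 1): {self.ad_base_prevalence}"
            )
        for field in ("n_sample_exposure", "n_sample_outcome"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"{field} must be positive")
        if abs(self.theta_ea_iq) >= 1 or abs(self.theta_ea_iq * self.theta_iq_ea) >= 1:
            raise ConfigurationError(
                "realized trait-trait coefficients too large for unit-variance scaling"
            )
        if self.selection not in ("pvalue", "oracle"):
            raise ConfigurationError(f"selection must be 'pvalue' or 'oracle': {self.selection}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigurationError(f"unknown scenario config keys: {bad}")
        raw = dict(raw)
        for key in ("maf_range", "confounder_strength"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Scenario library: the causal structures of the diagram catalogue.
#: (a) confounding of EA–AD by IQ; (b) mirror; (c) EA→IQ→AD full mediation;
#: (d) mirror; (e) pleiotropy through IQ; (f) mirror; (g) genetically driven
#: but causally disconnected traits; (h) joint direct effects with a
#: reciprocal EA↔IQ relationship.
_SCENARIO_DEFAULTS: dict[str, dict] = {
    # In (a)/(b) the contaminated panel's signal is carried by the *other*
    # trait's SNPs; the exposure-specific minority exists for multivariable
    # identifiability and gets a minority of the panel variance (h² 0.02 vs
    # the diagram-borne 0.15), so the spurious univariable association the
    # diagram describes is actually expressed.
    "a": dict(n_snps_ea=15, n_snps_iq=100, ea_panel_from_iq=85, h2_ea=0.02,
              theta_iq_ea=0.5, theta_iq_ad=-0.45),
    "b": dict(n_snps_ea=100, n_snps_iq=15, iq_panel_from_ea=85, h2_iq=0.02,
              theta_ea_iq=0.5, theta_ea_ad=-0.45),
    "c": dict(theta_ea_iq=0.5, theta_iq_ad=-0.45),
    "d": dict(theta_iq_ea=0.5, theta_ea_ad=-0.45),
    "e": dict(iq_cross_loading=0.5, cross_noise_sd=0.01, theta_iq_ad=-0.45),
    "f": dict(ea_cross_loading=0.5, cross_noise_sd=0.01, theta_ea_ad=-0.45),
    "g": dict(cross_noise_sd=0.03, pleiotropy_sd=0.02),
    "h": dict(theta_iq_ea=0.51, theta_ea_iq=0.57, theta_ea_ad=-0.2, theta_iq_ad=-0.3),
}


def scenario_config(scenario_id: str, **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from the scenario library (a–h)."""
    if scenario_id not in _SCENARIO_DEFAULTS:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; choose from {sorted(_SCENARIO_DEFAULTS)}"
        )
    params = dict(_SCENARIO_DEFAULTS[scenario_id], scenario_id=scenario_id)
    params.update(overrides)
    return ScenarioConfig(**params)


def replica_study_config(**overrides) -> ScenarioConfig:
    """SYNTHETIC replica of the education/intelligence/AD study design.

    This is a synthetic stand-in for the study's per-SNP supplementary
    tables, which are not redistributable: the reported effect sizes are
    used as *generative truths* (IQ→EA 0.51 SD/SD; EA→IQ 0.57 SD/SD, the
    directionality-filtered value; a direct IQ→AD effect of log(0.62) with
    no direct EA→AD effect — i.e. the EA effect fully mediated by IQ), and
    the instrument panels mirror the reported composition: a 148-SNP EA
    panel of which 125 act IQ-first, a 180-SNP IQ panel, 9 SNPs shared.
    Sample sizes are desk-scale but preserve per-instrument strength
    (z ≈ 6) and the case-enriched outcome-sample case fraction (0.314).
    """
    params = dict(
        scenario_id="replica",
        n_snps_ea=23,
        n_snps_iq=180,
        ea_panel_from_iq=125,
        panel_overlap=9,
        # Panel heritabilities and the exposure sample size are set so that
        # per-instrument strength matches the study's printed F statistics
        # (~43.5 for the EA-specific and ~50.45 for the IQ instruments).
        h2_ea=0.016,
        h2_iq=0.33,
        effect_distribution="fixed_magnitude",
        theta_iq_ea=0.51,
        theta_ea_iq=0.57,
        theta_ea_ad=0.0,
        theta_iq_ad=math.log(0.62),
        n_sample_exposure=63_000,
        n_sample_outcome=25_000,
        ad_base_prevalence=0.314,
        selection="oracle",
    )
    params.update(overrides)
    return ScenarioConfig(**params)


# ---------------------------------------------------------------------------
# Architecture (ground truth)


@dataclasses.dataclass
class GroundTruth:
    """Realized per-SNP effects, solved structural coefficients, and the
    implied (path-traced) instrument effects and causal totals."""

    config: ScenarioConfig
    snp_meta: pd.DataFrame  # snp_id, chrom, pos, effect_allele, other_allele, maf, group
    maf: np.ndarray
    a: np.ndarray  # per-allele direct effects on EA (SD units)
    b: np.ndarray  # per-allele direct effects on pre-feedback IQ
    g_ad: np.ndarray  # per-allele direct (pleiotropic) effects on AD log-odds
    t_ie: float  # internal IQ1 -> EA coefficient
    t_ei: float  # internal EA_own -> IQ coefficient
    s: float  # IQ rescaling factor restoring unit variance
    resid_sd_ea: float
    resid_sd_iq: float
    alpha_ad: float
    ea_panel: list[str]
    iq_panel: list[str]
    ad_marginalization: float = dataclasses.field(init=False)
    implied_beta_ea: np.ndarray = dataclasses.field(init=False)
    implied_beta_iq: np.ndarray = dataclasses.field(init=False)
    implied_beta_ad: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self):
        c = self.config
        # Path tracing: a copy of the effect allele shifts EA by a + t_ie·b,
        # pre-feedback IQ by b, post-feedback IQ by (b + t_ei·a)/s, and the
        # AD log-odds through both exposures plus the direct term.
        self.implied_beta_ea = self.a + self.t_ie * self.b
        self.implied_beta_iq = (self.b + self.t_ei * self.a) / self.s
        # The estimand of a per-SNP logistic GWAS is the *marginal* log odds
        # ratio, which — odds ratios being non-collapsible — is attenuated
        # relative to the conditional coefficient by a factor depending on
        # the variance of the rest of the linear predictor. Implied AD
        # effects and totals are therefore reported on the marginal scale.
        self.ad_marginalization = self._marginalization_factor()
        self.implied_beta_ad = self.ad_marginalization * (
            c.theta_ea_ad * self.implied_beta_ea
            + c.theta_iq_ad * self.implied_beta_iq
            + self.g_ad
        )

    def _marginalization_factor(self) -> float:
        """Small-effect attenuation of per-SNP marginal log-ORs.

        With the non-SNP part of the linear predictor ``e ~ N(0, σ²)``,
        the marginal logistic slope for a weak SNP is the conditional slope
        times ``E[μ(1−μ)] / (p̄(1−p̄))`` with ``μ = expit(α + e)``; the
        expectation is evaluated by Gauss–Hermite quadrature and σ² from the
        model's analytic covariance structure.
        """
        c = self.config
        c_ea, c_iq, c_ad = c.confounder_strength
        v = 2.0 * self.maf * (1.0 - self.maf)
        var_ea_own = 1.0 - self.t_ie**2 - 2.0 * self.t_ie * (
            float(np.sum(self.a * self.b * v)) + c_ea * c_iq
        )
        kappa = float(np.sum(self.a * self.b * v)) + c_ea * c_iq
        cov_ea_iq = (
            self.t_ie + self.t_ie * self.t_ei * kappa + kappa + self.t_ei * var_ea_own
        ) / self.s
        cov_ea_u = self.t_ie * c_iq + c_ea
        cov_iq_u = (c_iq + self.t_ei * c_ea) / self.s
        te, ti = c.theta_ea_ad, c.theta_iq_ad
        sigma2 = (
            te**2 + ti**2 + 2.0 * te * ti * cov_ea_iq
            + float(np.sum(self.g_ad**2 * v))
            + 2.0 * float(np.sum(self.g_ad * (te * self.implied_beta_ea
                                              + ti * self.implied_beta_iq) * v))
            + c_ad**2 + 2.0 * c_ad * (te * cov_ea_u + ti * cov_iq_u)
        )
        if sigma2 <= 1e-12:
            return 1.0
        nodes, weights = np.polynomial.hermite.hermgauss(64)
        e = math.sqrt(2.0 * sigma2) * nodes
        mu = expit(self.alpha_ad + e)
        pbar = float(weights @ mu / math.sqrt(math.pi))
        fbar = float(weights @ (mu * (1.0 - mu)) / math.sqrt(math.pi))
        return fbar / (pbar * (1.0 - pbar))

    # -- implied causal quantities -------------------------------------

    @property
    def total_iq_on_ea(self) -> float:
        return self.config.theta_iq_ea

    @property
    def total_ea_on_iq(self) -> float:
        return self.config.theta_ea_iq

    @property
    def total_ea_on_ad(self) -> float:
        """Total EA→AD marginal log-odds per SD: direct plus the IQ-mediated
        path, on the (non-collapsed) scale a logistic GWAS estimates."""
        return self.ad_marginalization * (
            self.config.theta_ea_ad + self.config.theta_ea_iq * self.config.theta_iq_ad
        )

    @property
    def total_iq_on_ad(self) -> float:
        return self.ad_marginalization * (
            self.config.theta_iq_ad + self.config.theta_iq_ea * self.config.theta_ea_ad
        )

    @property
    def mvmr_direct(self) -> tuple[float, float]:
        """(EA, IQ) direct effects conditional on the other exposure, on the
        marginal log-odds scale."""
        return (
            self.ad_marginalization * self.config.theta_ea_ad,
            self.ad_marginalization * self.config.theta_iq_ad,
        )

    def _betas_for(self, trait: str) -> np.ndarray:
        return {
            EA: self.implied_beta_ea, IQ: self.implied_beta_iq, AD: self.implied_beta_ad
        }[trait]

    def implied_ivw(self, panel: list[str], exposure: str, outcome: str) -> tuple[float, bool]:
        """Expected IVW estimate over a panel, and whether the per-SNP
        ratios are homogeneous (so the value is also the per-SNP truth).

        Expected weights are proportional to the allele variance
        ``2·maf·(1−maf)`` — outcome SEs scale as its inverse square root —
        which is exact for homogeneous panels and a first-order expectation
        otherwise.
        """
        idx = self.snp_meta.set_index("snp_id").index.get_indexer(panel)
        bx = self._betas_for(exposure)[idx]
        by = self._betas_for(outcome)[idx]
        v = 2.0 * self.maf[idx] * (1.0 - self.maf[idx])
        if np.all(bx == 0):
            raise MRKitError(f"panel has no implied effect on {exposure}")
        value = float(np.sum(v * bx * by) / np.sum(v * bx**2))
        nz = bx != 0
        ratios = by[nz] / bx[nz]
        homogeneous = bool(nz.all() and np.ptp(ratios) < 1e-9)
        return value, homogeneous


def _scaled_effects(
    rng, k: int, total_var: float, v: np.ndarray, distribution: str = "normal"
) -> np.ndarray:
    """Per-allele effects for k SNPs with Σ effect²·v = total_var exactly.

    ``normal`` draws give χ²-distributed per-SNP contributions (a polygenic
    spectrum); ``fixed_magnitude`` gives every SNP the same r² with a random
    sign, emulating a lead-SNP list thresholded at genome-wide significance
    (no weak tail).
    """
    if k == 0 or total_var == 0:
        return np.zeros(k)
    if distribution == "fixed_magnitude":
        sign = rng.choice([-1.0, 1.0], size=k)
        return sign * np.sqrt(total_var / (k * v))
    raw = rng.standard_normal(k)
    raw[raw == 0] = 1e-12
    scale = math.sqrt(total_var / float(np.sum(raw**2 * v)))
    return raw * scale


def draw_architecture(config: ScenarioConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw per-SNP effects and solve the structural normalization."""
    c = config
    n_b = c.n_snps_iq + max(c.ea_panel_from_iq - c.panel_overlap, 0)
    n_a = c.n_snps_ea + max(c.iq_panel_from_ea - c.panel_overlap, 0)
    m = n_a + n_b
    if m == 0:
        raise ConfigurationError("scenario has no SNPs")

    maf = rng.uniform(*c.maf_range, size=m)
    v = 2.0 * maf * (1.0 - maf)
    a = np.zeros(m)
    b = np.zeros(m)
    ai = np.arange(0, n_a)  # EA-direct group
    bi = np.arange(n_a, m)  # IQ-direct group
    a[ai] = _scaled_effects(rng, n_a, c.h2_ea, v[ai], c.effect_distribution)
    b[bi] = _scaled_effects(rng, n_b, c.h2_iq, v[bi], c.effect_distribution)
    if c.iq_cross_loading != 0 or c.cross_noise_sd > 0:
        b[ai] = c.iq_cross_loading * a[ai] + rng.normal(0, c.cross_noise_sd, size=n_a)
    if c.ea_cross_loading != 0 or c.cross_noise_sd > 0:
        a[bi] = c.ea_cross_loading * b[bi] + rng.normal(0, c.cross_noise_sd, size=n_b)
    g_ad = np.zeros(m)
    if c.pleiotropy_mean != 0 or c.pleiotropy_sd > 0:
        g_ad = rng.normal(c.pleiotropy_mean, c.pleiotropy_sd, size=m)

    c_ea, c_iq, c_ad = c.confounder_strength
    var_g_iq1 = float(np.sum(b**2 * v))
    var_g_ea = float(np.sum(a**2 * v))
    kappa = float(np.sum(a * b * v)) + c_ea * c_iq  # Cov(IQ1, EA_own)

    # Solve the IQ rescaling factor s from the realized-scale coefficients:
    # s²(1−T_ei²) − 2·T_ei·κ·(1−T_ei·T_ie)·s − (1−T_ei²·T_ie²) = 0.
    T_ie, T_ei = c.theta_iq_ea, c.theta_ea_iq
    qa = 1.0 - T_ei**2
    qb = -2.0 * T_ei * kappa * (1.0 - T_ei * T_ie)
    qc = -(1.0 - (T_ei * T_ie) ** 2)
    disc = qb**2 - 4.0 * qa * qc
    if qa <= 0 or disc < 0:
        raise ConfigurationError("no unit-variance scaling exists for these coefficients")
    s = (-qb + math.sqrt(disc)) / (2.0 * qa)
    t_ie = T_ie / s
    t_ei = T_ei * s

    resid_var_iq1 = 1.0 - var_g_iq1 - c_iq**2
    if resid_var_iq1 <= 0:
        raise ConfigurationError(
            "IQ variance budget exceeds 1: "
            f"genetic {var_g_iq1:.4f} + confounder {c_iq**2:.4f} >= 1"
        )
    var_ea_own = 1.0 - t_ie**2 - 2.0 * t_ie * kappa
    resid_var_ea = var_ea_own - var_g_ea - c_ea**2
    if resid_var_ea <= 0:
        raise ConfigurationError(
            "EA variance budget exceeds 1: "
            f"IQ-path {t_ie**2:.4f} + 2·cov {2 * t_ie * kappa:.4f} + "
            f"genetic {var_g_ea:.4f} + confounder {c_ea**2:.4f} >= 1"
        )

    ids = [f"rs{i + 1}" for i in range(m)]
    chrom = [str(1 + i % 22) for i in range(m)]
    pos = [1_000_000 + 25_000_000 * (i // 22) for i in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    meta = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "maf": maf,
            "group": ["ea_direct"] * n_a + ["iq_direct"] * n_b,
        }
    )

    # Panels: designed instrument lists. The EA panel may contain IQ-acting
    # SNPs (and vice versa), including a block shared with the other panel.
    b_ids = [ids[i] for i in bi]
    a_ids = [ids[i] for i in ai]
    iq_panel = b_ids[: c.n_snps_iq]
    ea_panel = a_ids[: c.n_snps_ea]
    if c.ea_panel_from_iq > 0:
        ea_panel = ea_panel + b_ids[: c.panel_overlap] + b_ids[
            c.n_snps_iq: c.n_snps_iq + c.ea_panel_from_iq - c.panel_overlap
        ]
    if c.iq_panel_from_ea > 0:
        iq_panel = iq_panel + a_ids[: c.panel_overlap] + a_ids[
            c.n_snps_ea: c.n_snps_ea + c.iq_panel_from_ea - c.panel_overlap
        ]

    return GroundTruth(
        config=c, snp_meta=meta, maf=maf, a=a, b=b, g_ad=g_ad,
        t_ie=t_ie, t_ei=t_ei, s=s,
        resid_sd_ea=math.sqrt(resid_var_ea),
        resid_sd_iq=math.sqrt(resid_var_iq1),
        alpha_ad=float(logit(c.ad_base_prevalence)),
        ea_panel=ea_panel, iq_panel=iq_panel,
    )


# ---------------------------------------------------------------------------
# Individual-level simulation


@dataclasses.dataclass
class Individuals:
    genotypes: np.ndarray  # (n, m) effect-allele dosages
    ea: np.ndarray
    iq: np.ndarray
    ad: np.ndarray
    confounder: np.ndarray


def simulate_individuals(
    config: ScenarioConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    architecture: GroundTruth | None = None,
) -> tuple[Individuals, GroundTruth]:
    """Simulate one sample of individuals (genotypes, EA, IQ, AD status).

    The architecture (per-SNP effects) is drawn once unless supplied, so
    multiple samples can share one generative law. Reproducible under seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = architecture if architecture is not None else draw_architecture(config, rng)
    n = n if n is not None else config.n_sample_exposure
    c = config
    c_ea, c_iq, c_ad = c.confounder_strength

    # Binomial(2, maf) as the sum of two Bernoulli draws (much faster than
    # np.random.binomial for large matrices; same distribution).
    m = len(truth.maf)
    geno = (
        (rng.random((n, m)) < truth.maf).astype(np.int8)
        + (rng.random((n, m)) < truth.maf).astype(np.int8)
    )
    gc = geno - 2.0 * truth.maf  # centered dosages; GWAS uses raw dosages
    u = rng.standard_normal(n)
    iq1 = gc @ truth.b + c_iq * u + truth.resid_sd_iq * rng.standard_normal(n)
    ea_own = gc @ truth.a + c_ea * u + truth.resid_sd_ea * rng.standard_normal(n)
    ea = truth.t_ie * iq1 + ea_own
    iq = (iq1 + truth.t_ei * ea_own) / truth.s
    eta = (
        truth.alpha_ad
        + c.theta_ea_ad * ea
        + c.theta_iq_ad * iq
        + gc @ truth.g_ad
        + c_ad * u
    )
    ad = (rng.random(n) < expit(eta)).astype(np.int8)
    return Individuals(geno, ea, iq, ad, u), truth


# ---------------------------------------------------------------------------
# Per-SNP association estimation


def _linear_gwas(geno: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Closed-form simple linear regression per SNP (vectorized)."""
    n = len(y)
    g = geno.astype(np.float64)
    gm = g.mean(axis=0)
    gc = g - gm
    sxx = np.einsum("ij,ij->j", gc, gc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    yc = y - y.mean()
    beta = (yc @ gc) / sxx_safe
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx_safe)
    # exact fits get a tiny positive SE (se > 0 is an output invariant);
    # monomorphic SNPs get +inf
    se = np.where(mono, np.inf, np.maximum(se, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(np.isfinite(se), beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, pval, mono


def _logistic_gwas(
    geno: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, ...]:
    """Per-SNP univariate logistic regression by Newton scoring.

    A dosage covariate takes only the values 0/1/2, so the per-SNP
    likelihood depends on the data only through the 3×2 genotype × outcome
    contingency table; Newton scoring runs on those sufficient statistics
    ((3, m) arrays), giving exactly the per-SNP ML fit at a fraction of the
    cost of iterating over the full individual-level matrix.
    """
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise MRKitError("binary phenotype has no variation")
    m = geno.shape[1]
    ymask = np.asarray(y, np.int8) == 1
    counts = np.empty((3, m))
    cases = np.empty((3, m))
    for k in (0, 1, 2):
        mask = geno == k
        counts[k] = mask.sum(axis=0)
        cases[k] = (mask & ymask[:, None]).sum(axis=0)
    mono = (counts > 0).sum(axis=0) <= 1
    dose = np.array([0.0, 1.0, 2.0])[:, None]
    b0 = np.full(m, logit(ybar))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        mu = expit(b0 + dose * b1)  # (3, m)
        resid = cases - counts * mu
        grad0 = resid.sum(axis=0)
        grad1 = (dose * resid).sum(axis=0)
        w = counts * mu * (1.0 - mu)
        h00 = w.sum(axis=0)
        h01 = (dose * w).sum(axis=0)
        h11 = (dose**2 * w).sum(axis=0)
        det = h00 * h11 - h01**2
        ok = det > 0
        det_safe = np.where(ok, det, 1.0)
        step0 = np.where(ok, (h11 * grad0 - h01 * grad1) / det_safe,
                         grad0 / np.maximum(h00, 1e-12))
        step1 = np.where(ok, (h00 * grad1 - h01 * grad0) / det_safe, 0.0)
        b0 += step0
        b1 += step1
        if max(np.max(np.abs(step0)), np.max(np.abs(step1))) < tol:
            break
    mu = expit(b0 + dose * b1)
    w = counts * mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (dose * w).sum(axis=0)
    h11 = (dose**2 * w).sum(axis=0)
    det = h00 * h11 - h01**2
    se = np.sqrt(np.where(det > 0, h00 / np.where(det > 0, det, 1.0), np.inf))
    se = np.where(mono, np.inf, se)
    b1 = np.where(mono, 0.0, b1)
    z = np.where(np.isfinite(se), b1 / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return b1, se, pval, mono


def gwas_summary(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str,
    snp_meta: pd.DataFrame,
    trait_name: str,
    trait_sd_label: str = "",
) -> SummaryStatsTable:
    """Per-SNP association estimates as a summary-statistics table.

    Continuous traits: simple OLS beta/SE with t p-values. Binary traits:
    univariate logistic regression log-OR/SE with Wald p-values. EAF is the
    sample effect-allele frequency; monomorphic SNPs are emitted with
    ``beta = 0, se = +inf, pval = 1`` and a ``monomorphic`` flag and are
    never selected as instruments.
    """
    if genotypes.shape[0] != len(phenotype):
        raise ConfigurationError("phenotype length does not match genotype rows")
    if genotypes.shape[1] != len(snp_meta):
        raise ConfigurationError("snp_meta length does not match genotype columns")
    if trait_type == "continuous":
        beta, se, pval, mono = _linear_gwas(genotypes, np.asarray(phenotype, float))
    elif trait_type == "binary":
        beta, se, pval, mono = _logistic_gwas(genotypes, np.asarray(phenotype))
    else:
        raise ConfigurationError(f"unknown trait_type {trait_type!r}")
    pval = np.clip(pval, 1e-300, 1.0)
    beta = np.where(mono, 0.0, beta)
    pval = np.where(mono, 1.0, pval)
    df = pd.DataFrame(
        {
            "snp_id": snp_meta["snp_id"].to_numpy(),
            "chrom": snp_meta["chrom"].to_numpy(),
            "pos": snp_meta["pos"].to_numpy(),
            "effect_allele": snp_meta["effect_allele"].to_numpy(),
            "other_allele": snp_meta["other_allele"].to_numpy(),
            "eaf": genotypes.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(genotypes.shape[0]),
            "monomorphic": mono,
        }
    )
    return SummaryStatsTable(trait_name, trait_type, df, trait_sd_label)


# ---------------------------------------------------------------------------
# Two-sample study assembly


@dataclasses.dataclass
class TwoSampleStudy:
    """Summary statistics for a two-sample design with known ground truth.

    ``exposure_tables`` hold every SNP's association with EA and IQ in
    sample 1 (the exposure sample); ``outcome_tables`` the associations with
    EA, IQ and AD in the disjoint sample 2. ``panels`` are the selected
    instrument lists per exposure.
    """

    config: ScenarioConfig
    truth: GroundTruth
    exposure_tables: dict[str, SummaryStatsTable]
    outcome_tables: dict[str, SummaryStatsTable]
    panels: dict[str, list[str]]

    def instruments(self, trait: str) -> SummaryStatsTable:
        """Instrument rows (sample-1 estimates) for one exposure panel."""
        return self.exposure_tables[trait].subset(self.panels[trait])


def make_two_sample_study(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> TwoSampleStudy:
    """Simulate a complete two-sample summary-statistics study.

    Two disjoint samples are drawn from the same generative law; exposure
    associations are estimated in sample 1 and outcome associations in
    sample 2. Instruments are the SNPs passing ``p_threshold`` for their
    exposure in sample 1 (``selection="pvalue"``) or the designed panel
    lists (``selection="oracle"``). Identical seeds give identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = draw_architecture(config, rng)
    sample1, _ = simulate_individuals(config, config.n_sample_exposure, rng, truth)
    sample2, _ = simulate_individuals(config, config.n_sample_outcome, rng, truth)

    meta = truth.snp_meta
    exposure_tables = {
        EA: gwas_summary(sample1.genotypes, sample1.ea, "continuous", meta, EA,
                         trait_sd_label="1 SD of schooling"),
        IQ: gwas_summary(sample1.genotypes, sample1.iq, "continuous", meta, IQ,
                         trait_sd_label="1 SD of test score"),
    }
    outcome_tables = {
        EA: gwas_summary(sample2.genotypes, sample2.ea, "continuous", meta, EA,
                         trait_sd_label="1 SD of schooling"),
        IQ: gwas_summary(sample2.genotypes, sample2.iq, "continuous", meta, IQ,
                         trait_sd_label="1 SD of test score"),
        AD: gwas_summary(sample2.genotypes, sample2.ad, "binary", meta, AD),
    }

    panels: dict[str, list[str]] = {}
    for trait, designed in ((EA, truth.ea_panel), (IQ, truth.iq_panel)):
        tab = exposure_tables[trait].df
        usable = set(tab.loc[~tab["monomorphic"].astype(bool), "snp_id"])
        if config.selection == "oracle":
            panels[trait] = [s for s in designed if s in usable]
        else:
            hits = tab[(tab["pval"] < config.p_threshold) & ~tab["monomorphic"].astype(bool)]
            panels[trait] = hits["snp_id"].tolist()
        if not panels[trait]:
            raise MRKitError(
                f"no instruments for {trait} survived selection "
                f"(p < {config.p_threshold}); raise the threshold or sample size"
            )
    return TwoSampleStudy(config, truth, exposure_tables, outcome_tables, panels)
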