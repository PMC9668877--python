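"""Synthetic cohort and methylome generator with known ground truth.

Emulates the study conditions of a trauma-exposed, all-female cohort of
97 participants: adverse social exposure (ASE) marginals (childhood
trauma questionnaire total, adult traumatic events inventory, household
income, educational attainment, employment/disability), four genomic
ancestry dimensions, 16 fronto-limbic brain morphometry outcomes, and an
EPIC-like methylation matrix with planted co-methylated probe modules,
leukocyte-composition structure, covariate and smoking effects, and a
planted exposure -> module -> morphometry mediation path.

Marginal distributions are calibrated so the *truncated* draw reproduces
the target mean/SD on the target range: the CTQ total uses a shifted
truncated gamma (a truncated normal on [25, 93] cannot attain mean 40.5
with SD 15.4 — the distribution is strongly right-skewed), the TEI and
age use moment-matched truncated normals. Where the printed dispersion
is unattainable on the printed range for any smooth unimodal law (age),
the mean is matched exactly and the SD as closely as the family allows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import CELL_TYPES, MethylationMatrix, ValidationError
from .preprocess import m_to_beta

# ---------------------------------------------------------------------------
# marginal calibration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Latent (mu, sigma) so the [lo, hi]-truncated normal has the target
    mean, and the target SD where attainable.

    Falls back to a mean-exact / SD-closest solution when the target SD
    exceeds the family's supremum on the interval (the uniform limit).
    """

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def resid(p):
        m, s = moments(p[0], np.exp(p[1]))
        return [m - mean, s - sd]

    sol, info, ier, _ = optimize.fsolve(resid, [mean, np.log(sd)], full_output=True)
    if ier == 1 and max(abs(np.asarray(resid(sol)))) < 1e-6:
        return float(sol[0]), float(np.exp(sol[1]))

    # mean-exact fallback: for each sigma solve mu, keep the sigma whose SD
    # comes closest to the target
    def mu_for_mean(sigma: float) -> float:
        lo_mu, hi_mu = lo - 50 * sigma, hi + 50 * sigma
        return optimize.brentq(lambda mu: moments(mu, sigma)[0] - mean, lo_mu, hi_mu, xtol=1e-10)

    best = None
    for sigma in np.geomspace(sd / 4, 50 * (hi - lo), 60):
        mu = mu_for_mean(sigma)
        gap = abs(moments(mu, sigma)[1] - sd)
        if best is None or gap < best[0]:
            best = (gap, mu, sigma)
    return float(best[1]), float(best[2])


@lru_cache(maxsize=None)
def truncgamma_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """(shape, scale) of a gamma shifted to ``lo`` and truncated at ``hi``
    whose truncated mean/SD equal the targets."""
    U = hi - lo
    tm, tsd = mean - lo, sd

    def moments(k: float, theta: float) -> tuple[float, float]:
        u = U / theta
        z0 = special.gammainc(k, u)
        m1 = k * theta * special.gammainc(k + 1, u) / z0
        m2 = k * (k + 1) * theta**2 * special.gammainc(k + 2, u) / z0
        return m1, np.sqrt(m2 - m1**2)

    def resid(p):
        m, s = moments(np.exp(p[0]), np.exp(p[1]))
        return [m - tm, s - tsd]

    sol, info, ier, msg = optimize.fsolve(resid, np.log([(tm / tsd) ** 2, tsd**2 / tm]), full_output=True)
    if ier != 1 or max(abs(np.asarray(resid(sol)))) > 1e-6:
        raise ValidationError(
            f"cannot calibrate truncated gamma to mean {mean}, sd {sd} on [{lo}, {hi}]: {msg}"
        )
    return float(np.exp(sol[0])), float(np.exp(sol[1]))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    mu, sigma = truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)

def _truncgamma_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    k, theta = truncgamma_params(mean, sd, lo, hi)
    cap = stats.gamma.cdf(hi - lo, k, scale=theta)
    return lo + stats.gamma.ppf(u * cap, k, scale=theta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

INCOME_LEVELS = ("low", "mid", "high")  # $0-499 / $500-999 / $1000+ per month
EDUCATION_LEVELS = ("less_hs", "hs_ged", "more_hs")
EMPLOYMENT_LEVELS = ("employed", "disabled", "unemployed")

ASE_TERMS = ("income_low", "education_low", "ctq", "tei")

#: mean leukocyte composition of adult whole blood and the Dirichlet
#: concentration controlling inter-individual variability
CELL_MEAN_PROPS = (0.58, 0.07, 0.05, 0.05, 0.15, 0.10)
CELL_CONCENTRATION = 60.0


@dataclass(frozen=True)
class MorphometrySpec:
    """Marginal mean/sd of one brain outcome plus planted standardized
    ASE effects (keys from :data:`ASE_TERMS`)."""

    mean: float
    sd: float
    effects: Mapping[str, float] = field(default_factory=dict)


def default_morphometry_specs() -> dict[str, MorphometrySpec]:
    """The 16 fronto-limbic outcomes: bilateral-average hippocampus and
    amygdala volumes (mm^3) and surface area (mm^2) / cortical thickness
    (mm) for seven Desikan frontal subregions. Means/SDs are typical
    adult values; no ASE effects are planted by default."""
    specs = {
        "hippocampus_volume": (4100.0, 380.0),
        "amygdala_volume": (1600.0, 180.0),
        "fp_sa": (1300.0, 160.0),
        "mofc_sa": (2800.0, 320.0),
        "lofc_sa": (4300.0, 470.0),
        "sfg_sa": (7300.0, 800.0),
        "rmfg_sa": (5700.0, 620.0),
        "racc_sa": (1250.0, 210.0),
        "cacc_sa": (1050.0, 190.0),
        "fp_ct": (2.75, 0.22),
        "mofc_ct": (2.45, 0.16),
        "lofc_ct": (2.65, 0.15),
        "sfg_ct": (2.75, 0.16),
        "rmfg_ct": (2.45, 0.14),
        "racc_ct": (2.85, 0.20),
        "cacc_ct": (2.65, 0.19),
    }
    return {name: MorphometrySpec(m, s) for name, (m, s) in specs.items()}


VOLUME_OUTCOMES = ("hippocampus_volume", "amygdala_volume")
MORPHOMETRY_OUTCOMES = tuple(default_morphometry_specs())


def _check_simplex(name: str, probs: Sequence[float]) -> None:
    p = np.asarray(probs, dtype=float)
    if len(p) != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise ValidationError(f"{name} must be a 3-simplex summing to 1, got {probs}")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for the phenotype table; defaults reproduce the
    study's published marginals."""

    n_samples: int = 97
    age_mean: float = 40.0
    age_sd: float = 12.5
    age_range: tuple[float, float] = (19.0, 62.0)
    ctq_mean: float = 40.5
    ctq_sd: float = 15.4
    ctq_min: float = 25.0
    ctq_max: float = 93.0
    tei_mean: float = 4.2
    tei_sd: float = 2.3
    tei_range: tuple[float, float] = (0.0, 10.7)
    income_probs: tuple[float, float, float] = (0.30, 0.36, 0.34)
    education_probs: tuple[float, float, float] = (0.15, 0.30, 0.55)
    employment_probs: tuple[float, float, float] = (0.33, 0.07, 0.60)
    n_ancestry_dims: int = 4
    icv_mean: float = 1.4e6
    icv_sd: float = 1.3e5
    morphometry_specs: Mapping[str, MorphometrySpec] = field(
        default_factory=default_morphometry_specs
    )
    exposure_correlation: float = 0.0  # shared-adversity copula correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        for name in ("income_probs", "education_probs", "employment_probs"):
            _check_simplex(name, getattr(self, name))
        for name in ("age_sd", "ctq_sd", "tei_sd", "icv_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.ctq_min < self.ctq_max:
            raise ValidationError("ctq_min must be below ctq_max")
        if not 0.0 <= self.exposure_correlation < 1.0:
            raise ValidationError("exposure_correlation must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedMediation:
    """One exposure -> module -> outcome path on the standardized scale.

    ``a_path`` links the standardized exposure to the module latent
    factor, ``b_path`` the factor to the standardized outcome, and
    ``c_prime`` is the residual direct effect, so the planted total
    effect is exactly ``a*b + c_prime`` per SD of exposure.
    """

    exposure: str = "ctq"
    module_index: int = 0
    outcome: str = "rmfg_sa"
    a_path: float = 0.35
    b_path: float = -0.45
    c_prime: float = -0.10


@dataclass(frozen=True)
class MethylomeConfig:
    """Generator settings for the EPIC-like probe matrix."""

    n_probes: int = 2000
    module_sizes: tuple[int, ...] = (15, 15, 15, 15, 15, 15, 15, 15)
    module_latent_sd: float = 1.0
    probe_noise_sd: float = 1.0 / 3.0  # latent/noise ratio 3
    planted_mediation: PlantedMediation | None = field(default_factory=PlantedMediation)
    # covariate -> (fraction of probes affected, per-probe effect sd in
    # M units per covariate SD)
    covariate_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"age": (0.2, 0.3)}
    )
    n_smoking_probes: int = 26
    smoking_effect_sd: float = 0.4  # M units per SD of the smoking latent
    frac_chrXY: float = 0.03
    frac_cross_reactive: float = 0.02
    frac_bloodbrain_pass: float = 0.5
    probes_per_gene: float = 3.0
    #: when False, the per-sample cell-mixture baseline is replaced by a
    #: fixed per-probe level, leaving a pure factor model (useful for
    #: clean recovery experiments)
    include_cell_baseline: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_probes:
            raise ValidationError("module sizes exceed probe count")
        if any(s < 2 for s in self.module_sizes):
            raise ValidationError("every module needs >= 2 probes")
        for name in ("frac_chrXY", "frac_cross_reactive", "frac_bloodbrain_pass"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.planted_mediation is not None:
            pm = self.planted_mediation
            if not 0 <= pm.module_index < len(self.module_sizes):
                raise ValidationError("mediation module index out of range")
            if abs(pm.a_path) > 1.0:
                raise ValidationError("|a_path| must be <= 1 on the standardized scale")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cell_proportions: pd.DataFrame | None = None
    morphometry_effects: dict[str, dict[str, float]] | None = None
    module_labels: pd.Series | None = None
    latent_factors: pd.DataFrame | None = None
    loadings: pd.Series | None = None
    mediation: PlantedMediation | None = None
    covariate_effects: pd.DataFrame | None = None
    smoking_effects: pd.DataFrame | None = None

    @property
    def planted_total_effect(self) -> float | None:
        if self.mediation is None:
            return None
        return self.mediation.a_path * self.mediation.b_path + self.mediation.c_prime


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def _categorical_from_u(u: np.ndarray, probs: Sequence[float], levels: Sequence[str]) -> np.ndarray:
    cuts = np.cumsum(probs)
    idx = np.searchsorted(cuts[:-1], u, side="right")
    return np.asarray(levels, dtype=object)[idx]


def standardized(x: pd.Series | np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def simulate_phenotypes(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the phenotype table: exposures, covariates, true leukocyte
    proportions, a smoking latent, and the 16 morphometry outcomes.

    ASEs are independent by default; ``exposure_correlation`` > 0 couples
    them through a shared standard-normal adversity factor via a Gaussian
    copula (adverse categories load positively on the factor).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]

    rho = config.exposure_correlation
    load = np.sqrt(rho)
    g = rng.standard_normal(n)

    def latent() -> np.ndarray:
        z = rng.standard_normal(n)
        return load * g + np.sqrt(1.0 - rho) * z if rho > 0 else z

    u_ctq, u_tei = stats.norm.cdf(latent()), stats.norm.cdf(latent())
    # adverse categories sit at the low quantile end, so flip the latent
    u_inc, u_edu, u_emp = (stats.norm.cdf(-latent()) for _ in range(3))

    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    pheno["age"] = _truncnorm_ppf(
        stats.norm.cdf(rng.standard_normal(n)), config.age_mean, config.age_sd, *config.age_range
    )
    pheno["ctq_total"] = _truncgamma_ppf(u_ctq, config.ctq_mean, config.ctq_sd, config.ctq_min, config.ctq_max)
    pheno["tei"] = _truncnorm_ppf(u_tei, config.tei_mean, config.tei_sd, *config.tei_range)
    pheno["income"] = _categorical_from_u(u_inc, config.income_probs, INCOME_LEVELS)
    pheno["education"] = _categorical_from_u(u_edu, config.education_probs, EDUCATION_LEVELS)
    emp_u = stats.norm.cdf(-latent()) if rho > 0 else u_emp
    pheno["employment"] = _categorical_from_u(
        emp_u, (config.employment_probs[2], config.employment_probs[1], config.employment_probs[0]),
        (EMPLOYMENT_LEVELS[2], EMPLOYMENT_LEVELS[1], EMPLOYMENT_LEVELS[0]),
    )
    for k in range(1, config.n_ancestry_dims + 1):
        pheno[f"ancestry_{k}"] = rng.standard_normal(n)
    pheno["icv"] = config.icv_mean + config.icv_sd * rng.standard_normal(n)
    pheno["smoking"] = rng.standard_normal(n)  # latent driving the proxy probes

    cells = pd.DataFrame(
        rng.dirichlet(CELL_CONCENTRATION * np.asarray(CELL_MEAN_PROPS), size=n),
        index=pheno.index,
        columns=list(CELL_TYPES),
    )

    term_columns = _ase_term_columns(pheno)
    effects_used: dict[str, dict[str, float]] = {}
    for name, spec in config.morphometry_specs.items():
        lin = np.zeros(n)
        var_planted = 0.0
        for term, beta in spec.effects.items():
            col, var_t = term_columns[term]
            lin += beta * col
            var_planted += beta**2 * var_t
        if var_planted > 1.0:
            raise ValidationError(f"planted effects on {name} exceed unit standardized variance")
        y_std = lin + np.sqrt(1.0 - var_planted) * rng.standard_normal(n)
        pheno[name] = spec.mean + spec.sd * y_std
        effects_used[name] = dict(spec.effects)

    truth = GroundTruth(cell_proportions=cells, morphometry_effects=effects_used)
    return pheno, truth


def _ase_term_columns(pheno: pd.DataFrame) -> dict[str, tuple[np.ndarray, float]]:
    """Planted-effect regressors and their theoretical variances: continuous
    exposures standardized (variance 1), adverse-category indicators left
    as 0/1 dummies (variance p(1-p) estimated empirically)."""
    cols: dict[str, tuple[np.ndarray, float]] = {
        "ctq": (standardized(pheno["ctq_total"]), 1.0),
        "tei": (standardized(pheno["tei"]), 1.0),
    }
    for term, col, level in (
        ("income_low", "income", "low"),
        ("education_low", "education", "less_hs"),
    ):
        d = (pheno[col] == level).to_numpy(dtype=float)
        p = d.mean()
        cols[term] = (d, p * (1.0 - p))
    return cols


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------


def simulate_cell_reference(probe_ids: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Synthetic leukocyte reference profiles (probes x cell types, beta
    scale). A fifth of probes are cell-discriminating with cell-specific
    M-value offsets; the rest share the baseline."""
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    base_m = rng.normal(0.0, 2.0, size=n)
    offsets = np.zeros((n, len(CELL_TYPES)))
    discr = rng.random(n) < 0.2
    offsets[discr] = rng.normal(0.0, 1.5, size=(discr.sum(), len(CELL_TYPES)))
    betas = m_to_beta(base_m[:, None] + offsets)
    return pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"), columns=list(CELL_TYPES))


@dataclass
class MethylomeSimulation:
    """Bundle returned by :func:`simulate_methylome`."""

    beta: MethylationMatrix
    annotation: pd.DataFrame
    phenotypes: pd.DataFrame  # copy with the b-path injected
    truth: GroundTruth
    cell_reference: pd.DataFrame
    smoking_effects: pd.DataFrame


def _probe_ids(n: int, rng: np.random.Generator) -> list[str]:
    nums = rng.choice(100_000_000, size=n, replace=False)
    return [f"cg{v:08d}" for v in nums]


def simulate_methylome(
    pheno: pd.DataFrame,
    config: MethylomeConfig,
    truth: GroundTruth | None = None,
) -> MethylomeSimulation:
    """Generate the beta matrix, probe annotation and ground truth.

    Probe M-values follow a factor model: a cell-composition baseline
    (mixture of reference profiles by each sample's true fractions), plus
    ``loading * f_m`` for module members, plus covariate and smoking
    effects, plus independent probe noise. For the mediation module the
    latent factor is ``a * std(exposure) + sqrt(1-a^2) * noise`` so the
    correlation structure encodes the a-path; the b-path and direct
    effect are injected into a copy of the phenotype table on the
    standardized outcome scale, preserving the outcome's configured
    marginal variance so the planted standardized effects are exact.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = len(pheno)
    truth = truth or GroundTruth()
    if truth.cell_proportions is None:
        truth.cell_proportions = pd.DataFrame(
            rng.dirichlet(CELL_CONCENTRATION * np.asarray(CELL_MEAN_PROPS), size=n_samples),
            index=pheno.index,
            columns=list(CELL_TYPES),
        )
    probes = _probe_ids(config.n_probes, rng)
    probe_index = pd.Index(probes, name="probe_id")

    reference = simulate_cell_reference(probes, seed=int(rng.integers(2**31)))
    W = truth.cell_proportions.loc[pheno.index].to_numpy()  # samples x cells
    resid_w = 1.0 - W.sum(axis=1)
    W_full = W + resid_w[:, None] * np.asarray(CELL_MEAN_PROPS)  # close the composition
    if not config.include_cell_baseline:
        W_full = np.tile(np.asarray(CELL_MEAN_PROPS), (n_samples, 1))
    base_beta = reference.to_numpy() @ W_full.T  # probes x samples
    M = np.log2(np.clip(base_beta, 1e-6, 1 - 1e-6) / (1 - np.clip(base_beta, 1e-6, 1 - 1e-6)))

    # module membership: random probes, labels 1..K
    labels = pd.Series(0, index=probe_index, dtype=int)
    member = rng.choice(config.n_probes, size=sum(config.module_sizes), replace=False)
    splits = np.split(member, np.cumsum(config.module_sizes)[:-1])
    pm = config.planted_mediation
    factors = {}
    loadings = pd.Series(0.0, index=probe_index)
    for k, idx in enumerate(splits, start=1):
        labels.iloc[idx] = k
        if pm is not None and k == pm.module_index + 1:
            x_std = standardized(pheno[_exposure_column(pm.exposure)])
            f = pm.a_path * x_std + np.sqrt(1.0 - pm.a_path**2) * rng.standard_normal(n_samples)
        else:
            f = rng.standard_normal(n_samples)
        f = standardized(f)  # exact unit sample variance in the truth
        factors[f"module_{k}"] = f
        lam = rng.uniform(0.7, 1.0, size=len(idx)) * rng.choice([-1.0, 1.0], size=len(idx))
        loadings.iloc[idx] = lam
        M[idx] += np.outer(lam, config.module_latent_sd * f)

    # covariate effects on a random subset of probes
    cov_rows = []
    for cov, (frac, effect_sd) in config.covariate_effects.items():
        affected = rng.random(config.n_probes) < frac
        eff = np.where(affected, rng.normal(0.0, effect_sd, size=config.n_probes), 0.0)
        M += np.outer(eff, standardized(pheno[cov]))
        cov_rows.append(pd.Series(eff, index=probe_index, name=cov))
    covariate_effects = pd.concat(cov_rows, axis=1) if cov_rows else pd.DataFrame(index=probe_index)

    # smoking proxy probes among the background
    background = np.flatnonzero(labels.to_numpy() == 0)
    smoke_idx = rng.choice(background, size=config.n_smoking_probes, replace=False)
    smoke_eff = rng.normal(0.0, config.smoking_effect_sd, size=config.n_smoking_probes)
    M[smoke_idx] += np.outer(smoke_eff, standardized(pheno["smoking"]))
    smoking_effects = pd.DataFrame(
        {"effect": smoke_eff}, index=probe_index[smoke_idx].rename("probe_id")
    )

    M += rng.normal(0.0, config.probe_noise_sd, size=M.shape)
    beta = MethylationMatrix(
        pd.DataFrame(m_to_beta(M), index=probe_index, columns=pheno.index), scale="beta"
    )

    annotation = _make_annotation(probe_index, labels, config, rng)

    pheno_out = pheno.copy()
    if pm is not None:
        pheno_out = _inject_b_path(pheno_out, pm, factors[f"module_{pm.module_index + 1}"])

    truth.module_labels = labels
    truth.latent_factors = pd.DataFrame(factors, index=pheno.index)
    truth.loadings = loadings
    truth.mediation = pm
    truth.covariate_effects = covariate_effects
    truth.smoking_effects = smoking_effects
    return MethylomeSimulation(beta, annotation, pheno_out, truth, reference, smoking_effects)


def _exposure_column(exposure: str) -> str:
    return {"ctq": "ctq_total", "tei": "tei"}.get(exposure, exposure)


def _inject_b_path(pheno: pd.DataFrame, pm: PlantedMediation, factor: np.ndarray) -> pd.DataFrame:
    """Rebuild the mediated outcome as ``b*f + c'*x + residual`` on the
    standardized scale, shrinking the pre-existing variation so the
    marginal variance is preserved and planted effects are exact."""
    y = pheno[pm.outcome].to_numpy(dtype=float)
    mean, sd = y.mean(), y.std(ddof=1)
    x_std = standardized(pheno[_exposure_column(pm.exposure)])
    planted_var = pm.b_path**2 + pm.c_prime**2 + 2 * pm.a_path * pm.b_path * pm.c_prime
    if planted_var > 1.0:
        raise ValidationError("planted mediation path exceeds unit standardized variance")
    y_std_new = (
        pm.b_path * factor
        + pm.c_prime * x_std
        + np.sqrt(1.0 - planted_var) * standardized(y)
    )
    pheno = pheno.copy()
    pheno[pm.outcome] = mean + sd * y_std_new
    return pheno


def _make_annotation(
    probe_index: pd.Index, labels: pd.Series, config: MethylomeConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(probe_index)
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=n).astype(object)
    background = labels.to_numpy() == 0
    n_xy = int(round(config.frac_chrXY * background.sum()))
    xy_idx = rng.choice(np.flatnonzero(background), size=n_xy, replace=False)
    chrom[xy_idx] = rng.choice(["chrX", "chrY"], size=n_xy)

    cross = np.zeros(n, dtype=int)
    cand = np.flatnonzero(background)
    n_cross = int(round(config.frac_cross_reactive * len(cand)))
    cross[rng.choice(cand, size=n_cross, replace=False)] = 1

    bb = rng.uniform(0.05, 1.0, size=n)
    n_pass = int(round(config.frac_bloodbrain_pass * background.sum()))
    bb[rng.choice(np.flatnonzero(background), size=n_pass, replace=False)] = rng.uniform(
        1e-6, 0.05, size=n_pass
    )
    bb[~background] = rng.uniform(1e-6, 0.05, size=(~background).sum())  # planted modules pass

    n_genes = max(1, int(round(n / config.probes_per_gene)))
    genes = rng.choice([f"GENE{i:05d}" for i in range(n_genes)], size=n)

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": rng.integers(10_000, 240_000_000, size=n),
            "gene": genes,
            "cross_reactive": cross,
            "bloodbrain_p": bb,
        },
        index=probe_index,
    )


# ---------------------------------------------------------------------------
# gene sets and fixture bundle
# ---------------------------------------------------------------------------


def make_gene_sets(
    annotation: pd.DataFrame,
    labels: pd.Series | None = None,
    n_sets: int = 40,
    size_range: tuple[int, int] = (25, 120),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over the measured-gene universe, plus one set
    collecting the genes of planted modules when labels are supplied."""
    rng = np.random.default_rng(seed)
    universe = sorted(annotation["gene"].unique())
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], min(size_range[1], len(universe)) + 1))
        sets[f"SET{i:03d}"] = sorted(rng.choice(universe, size=size, replace=False).tolist())
    if labels is not None and (labels > 0).any():
        module_genes = sorted(annotation.loc[labels[labels > 0].index, "gene"].unique())
        sets["PLANTED_MODULES"] = module_genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: Path | str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, f"{name} synthetic gene set", *genes]) + "\n")


def write_fixture_bundle(sim: MethylomeSimulation, outdir: Path | str) -> dict[str, Path]:
    """Write the full input bundle as plain-text files and return the paths.

    Matrices round-trip bit-exactly: pandas writes shortest-round-trip
    float representations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "cell_reference": outdir / "cell_reference.tsv",
        "smoking_effects": outdir / "smoking_effects.tsv",
        "truth": outdir / "truth.json",
    }
    sim.beta.values.to_csv(paths["beta"], sep="\t")
    sim.phenotypes.to_csv(paths["phenotypes"])
    sim.annotation.to_csv(paths["annotation"], sep="\t")
    sim.cell_reference.to_csv(paths["cell_reference"], sep="\t")
    sim.smoking_effects.to_csv(paths["smoking_effects"], sep="\t")
    sets = make_gene_sets(sim.annotation, sim.truth.module_labels)
    write_gmt(sets, paths["gene_sets"])

    truth = sim.truth
    payload = {
        "module_labels": truth.module_labels.to_dict(),
        "loadings": truth.loadings.to_dict(),
        "mediation": asdict(truth.mediation) if truth.mediation else None,
        "planted_total_effect": truth.planted_total_effect,
        "cell_proportions": truth.cell_proportions.to_dict(orient="index"),
        "morphometry_effects": truth.morphometry_effects,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
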