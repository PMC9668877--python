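"""Quasi-Bayesian Monte Carlo causal mediation for (exposure, mediator,
outcome) triples.

Two linear models are fit by OLS — the mediator model
``m ~ x + covariates`` and the outcome model ``y ~ x + m + covariates``
(no exposure-mediator interaction, so the product-of-coefficients
decomposition is exact). Coefficient vectors are then drawn from the
multivariate normal centred at the estimates with the estimated
coefficient covariance, independently for the two models. Each draw j
yields

    IDE_j = a_j * b_j * delta,   DE_j = c'_j * delta,   TE_j = IDE_j + DE_j

where ``a`` is the exposure coefficient in the mediator model, ``b`` the
mediator coefficient and ``c'`` the exposure coefficient in the outcome
model, and ``delta = treat - control`` is the exposure contrast. Point
estimates are draw means, confidence intervals are percentile intervals,
and p-values are two-sided zero-crossing proportions. The average
indirect effect (IDE), direct effect (DE) and total effect (TE) add
exactly, per draw and in the point estimates.

By default the contrast spans the observed exposure range (most- vs
least-exposed), so a TE of -0.98 SD is read as the outcome difference
between the highest and lowest exposure levels; a 1-SD contrast is
available via ``contrast="sd"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, ValidationError
from .screening import MediationCandidate, bh_flags
from .synthetic import standardized


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass(frozen=True)
class MediationRecord:
    """Mediation result for one (exposure, mediator, outcome) triple."""

    exposure: str
    mediator: str
    outcome: str
    ide: EffectEstimate
    de: EffectEstimate
    te: EffectEstimate
    proportion_mediated: float | None
    classification: str  # full | partial | none
    n_draws: int
    seed: int
    delta: float

    def __post_init__(self) -> None:
        if abs((self.ide.estimate + self.de.estimate) - self.te.estimate) > 1e-10:
            raise ValidationError("IDE + DE must equal TE")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS estimates and coefficient covariance; errors on rank deficiency."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("rank-deficient design in mediation model")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    return beta, sigma2 * XtX_inv


def _effect(draws: np.ndarray, level: float = 0.95) -> EffectEstimate:
    lo, hi = np.percentile(draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    p = 2 * min((draws <= 0).mean(), (draws >= 0).mean())
    return EffectEstimate(float(draws.mean()), float(lo), float(hi), float(min(1.0, p)))


def quasi_bayes_mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    *,
    treat_value: float | None = None,
    control_value: float | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    exposure: str = "x",
    mediator: str = "m",
    outcome: str = "y",
    alpha: float = 0.05,
) -> MediationRecord:
    """Run one quasi-Bayesian mediation analysis.

    ``treat_value``/``control_value`` default to the observed maximum and
    minimum of ``x``; results are deterministic under a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValidationError("x, m, y must be aligned")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} is small; intervals will be unstable", stacklevel=2)
    treat = float(x.max()) if treat_value is None else float(treat_value)
    control = float(x.min()) if control_value is None else float(control_value)
    if treat == control:
        raise ValidationError("treat and control values must differ")
    delta = treat - control

    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ones = np.ones((len(x), 1))
    Xm = np.hstack([ones, x[:, None]] + ([C] if C is not None else []))
    Xy = np.hstack([ones, x[:, None], m[:, None]] + ([C] if C is not None else []))

    bm, Vm = _ols(Xm, m)
    by, Vy = _ols(Xy, y)

    rng = np.random.default_rng(seed)
    draws_m = rng.multivariate_normal(bm, Vm, size=n_draws, method="cholesky")
    draws_y = rng.multivariate_normal(by, Vy, size=n_draws, method="cholesky")
    a = draws_m[:, 1]
    cprime = draws_y[:, 1]
    b = draws_y[:, 2]

    ide_draws = a * b * delta
    de_draws = cprime * delta
    te_draws = ide_draws + de_draws

    ide, de, te = _effect(ide_draws), _effect(de_draws), _effect(te_draws)
    prop = None if te.estimate == 0 else float(ide.estimate / te.estimate)
    record = MediationRecord(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        ide=ide,
        de=de,
        te=te,
        proportion_mediated=prop,
        classification="none",
        n_draws=n_draws,
        seed=seed,
        delta=delta,
    )
    return _with_classification(record, alpha=alpha)


def classify_mediation(
    p_te: float, p_ide: float, p_de: float, alpha: float = 0.05
) -> str:
    """Mediator status from the three effect p-values.

    ``full``: TE and IDE distinguishable from zero while the DE is not;
    ``partial``: all three distinguishable from zero; otherwise ``none``.
    """
    for name, p in (("TE", p_te), ("IDE", p_ide), ("DE", p_de)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} p-value outside [0, 1]")
    if p_te < alpha and p_ide < alpha:
        return "full" if p_de >= alpha else "partial"
    return "none"


def _with_classification(record: MediationRecord, alpha: float = 0.05) -> MediationRecord:
    from dataclasses import replace

    return replace(
        record,
        classification=classify_mediation(record.te.p, record.ide.p, record.de.p, alpha=alpha),
    )


def proportion_mediated(record: MediationRecord) -> float | None:
    """Point-estimate ratio IDE/TE (None when TE = 0); multiply by 100 and
    round for display as an integer percentage."""
    if record.te.estimate == 0:
        return None
    return record.ide.estimate / record.te.estimate


def proportion_mediated_percent(record: MediationRecord) -> int | None:
    prop = proportion_mediated(record)
    return None if prop is None else int(round(100 * prop))


def mediate_candidates(
    candidates: Sequence[MediationCandidate],
    eigengenes: pd.DataFrame,
    pheno: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    n_draws: int = 10_000,
    seed: int = 0,
    contrast: str = "range",
) -> list[MediationRecord]:
    """Mediate each gated (exposure, ME, outcome) triple.

    Continuous variables are standardized as in the screening arms; the
    exposure contrast defaults to its observed standardized range.
    """
    from .screening import ase_design

    records = []
    exposures = ase_design(pheno)
    for i, cand in enumerate(candidates):
        x = exposures[cand.exposure].to_numpy(dtype=float)
        m = standardized(eigengenes.loc[pheno.index, cand.mediator])
        y = standardized(pheno[cand.outcome])
        treat, control = (None, None) if contrast == "range" else (1.0, 0.0)
        records.append(
            quasi_bayes_mediate(
                x,
                m,
                y,
                covariates,
                treat_value=treat,
                control_value=control,
                n_draws=n_draws,
                seed=seed + i,
                exposure=cand.exposure,
                mediator=cand.mediator,
                outcome=cand.outcome,
            )
        )
    return records


def probewise_mediate(
    residual_matrix: MethylationMatrix,
    module_labels: pd.Series,
    candidate: MediationCandidate,
    module_index: int,
    pheno: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    n_draws: int = 10_000,
    seed: int = 0,
    q: float = 0.10,
    contrast: str = "range",
) -> pd.DataFrame:
    """Probe-level mediation across one (full-mediator) module.

    Each member probe's standardized residual M-value replaces the module
    eigengene as the mediator. BH control is applied jointly over the
    family of all member-probe IDE *and* DE p-values, so an 11-probe
    module yields a 22-test family.
    """
    from .screening import ase_design

    probes = module_labels.index[module_labels == module_index]
    probes = probes.intersection(residual_matrix.probe_ids)
    if len(probes) == 0:
        raise ValidationError(f"module {module_index} has no probes in the matrix")
    exposures = ase_design(pheno)
    x = exposures[candidate.exposure].to_numpy(dtype=float)
    y = standardized(pheno[candidate.outcome])
    treat, control = (None, None) if contrast == "range" else (1.0, 0.0)
    rows = []
    for i, probe in enumerate(probes):
        m = standardized(residual_matrix.values.loc[probe, pheno.index])
        rec = quasi_bayes_mediate(
            x,
            m,
            y,
            covariates,
            treat_value=treat,
            control_value=control,
            n_draws=n_draws,
            seed=seed + i,
            exposure=candidate.exposure,
            mediator=str(probe),
            outcome=candidate.outcome,
        )
        rows.append(rec)
    frame = mediation_frame(rows)
    family_p = np.concatenate([frame["ide_p"].to_numpy(), frame["de_p"].to_numpy()])
    flags = bh_flags(family_p, q=q)
    n = len(frame)
    frame["ide_bh"] = flags[:n]
    frame["de_bh"] = flags[n:]
    frame["bh_family_size"] = 2 * n
    return frame


def mediation_frame(records: Sequence[MediationRecord]) -> pd.DataFrame:
    """Tabular IDE/DE/TE report with CI bounds, p-values and status."""
    rows = []
    for r in records:
        rows.append(
            {
                "exposure": r.exposure,
                "mediator": r.mediator,
                "outcome": r.outcome,
                "ide": r.ide.estimate,
                "ide_ci_lower": r.ide.ci_lower,
                "ide_ci_upper": r.ide.ci_upper,
                "ide_p": r.ide.p,
                "de": r.de.estimate,
                "de_ci_lower": r.de.ci_lower,
                "de_ci_upper": r.de.ci_upper,
                "de_p": r.de.p,
                "te": r.te.estimate,
                "te_ci_lower": r.te.ci_lower,
                "te_ci_upper": r.te.ci_upper,
                "te_p": r.te.p,
                "proportion_mediated": r.proportion_mediated,
                "classification": r.classification,
                "n_draws": r.n_draws,
                "seed": r.seed,
                "delta": r.delta,
            }
        )
    return pd.DataFrame(rows)
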