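"""Three-arm standardized regression screens and FDR control.

Arm A regresses each of the 16 fronto-limbic morphometry outcomes on the
four adverse social exposures (ASEs) jointly (income and education as
dummy-coded categories, CTQ and TEI standardized) with ancestry, age and
employment as covariates (plus intracranial volume for the subcortical
volumes). Arm B regresses each module eigengene on the ASEs with
employment as the only covariate (the other confounders were removed by
residualization upstream). Arm C regresses each candidate outcome on
each candidate eigengene with age, ancestry, employment (and ICV where
applicable) as covariates. Nominal gates at alpha feed the mediation
stage; each arm forms a Benjamini-Hochberg test family at FDR q.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ValidationError
from .synthetic import (
    ASE_TERMS,
    EDUCATION_LEVELS,
    EMPLOYMENT_LEVELS,
    INCOME_LEVELS,
    MORPHOMETRY_OUTCOMES,
    VOLUME_OUTCOMES,
    standardized,
)


@dataclass(frozen=True)
class RegressionRecord:
    """One fitted term from one screening model."""

    outcome: str
    term: str
    beta: float
    se: float
    t: float
    p: float
    family: str
    bh_significant: bool = False


@dataclass
class TestFamily:
    """A named family of tests controlled jointly at FDR level q."""

    family_id: str
    records: list[RegressionRecord]
    q: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValidationError("q must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

#: term -> human-readable label mirroring the reporting convention
TERM_LABELS = {
    "income_low": "low household income",
    "education_low": "low educational attainment",
    "ctq": "childhood trauma burden",
    "tei": "adult trauma burden",
}


def _dummies(series: pd.Series, levels: Sequence[str], reference: str, prefix: str) -> pd.DataFrame:
    unknown = set(series.unique()) - set(levels)
    if unknown:
        raise ValidationError(f"unknown {prefix} levels: {sorted(unknown)}")
    out = {}
    for lev in levels:
        if lev == reference:
            continue
        out[f"{prefix}_{lev}"] = (series == lev).astype(float)
    return pd.DataFrame(out, index=series.index)


def ase_design(pheno: pd.DataFrame) -> pd.DataFrame:
    """The four exposures of interest: income/education dummies against
    the highest (least adverse) reference category, standardized CTQ and
    TEI. Column names carry the ASE term ids."""
    inc = _dummies(pheno["income"], INCOME_LEVELS, reference="high", prefix="income")
    edu = _dummies(pheno["education"], EDUCATION_LEVELS, reference="more_hs", prefix="education")
    edu = edu.rename(columns={"education_less_hs": "education_low", "education_hs_ged": "education_mid"})
    inc = inc.rename(columns={"income_mid": "income_mid"})
    design = pd.concat([inc, edu], axis=1)
    design["ctq"] = standardized(pheno["ctq_total"])
    design["tei"] = standardized(pheno["tei"])
    return design


def employment_design(pheno: pd.DataFrame) -> pd.DataFrame:
    return _dummies(pheno["employment"], EMPLOYMENT_LEVELS, reference="employed", prefix="employment")


def covariate_design_arm_a(pheno: pd.DataFrame, outcome: str, n_ancestry_dims: int = 4) -> pd.DataFrame:
    design = pd.DataFrame(index=pheno.index)
    for k in range(1, n_ancestry_dims + 1):
        design[f"ancestry_{k}"] = standardized(pheno[f"ancestry_{k}"])
    design["age"] = standardized(pheno["age"])
    design = pd.concat([design, employment_design(pheno)], axis=1)
    if outcome in VOLUME_OUTCOMES:
        design["icv"] = standardized(pheno["icv"])
    return design


def _fit_terms(
    y: np.ndarray,
    design: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    family: str,
) -> list[RegressionRecord]:
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from .preprocess import _collinear_columns

        bad = _collinear_columns(sm.add_constant(design, has_constant="add"))
        raise ValidationError(f"collinear design columns: {bad}")
    fit = sm.OLS(y, X).fit()
    names = ["const", *design.columns]
    records = []
    for term in terms:
        j = names.index(term)
        records.append(
            RegressionRecord(
                outcome=outcome,
                term=term,
                beta=float(fit.params[j]),
                se=float(fit.bse[j]),
                t=float(fit.tvalues[j]),
                p=float(fit.pvalues[j]),
                family=family,
            )
        )
    return records


# ---------------------------------------------------------------------------
# the three arms
# ---------------------------------------------------------------------------


def fit_arm_a(
    pheno: pd.DataFrame,
    outcomes: Sequence[str] = MORPHOMETRY_OUTCOMES,
    n_ancestry_dims: int = 4,
) -> list[RegressionRecord]:
    """ASEs -> brain morphometry. One model per outcome, all four ASEs
    jointly; returns one record per (outcome, ASE term): 16 x 4 = 64
    tests under the default outcome set."""
    records: list[RegressionRecord] = []
    for outcome in outcomes:
        if outcome not in pheno.columns:
            raise ValidationError(f"phenotype table lacks outcome {outcome!r}")
        y_raw = pheno[outcome].to_numpy(dtype=float)
        if y_raw.std(ddof=1) == 0:
            raise ValidationError(f"constant outcome {outcome!r}")
        design = pd.concat(
            [ase_design(pheno), covariate_design_arm_a(pheno, outcome, n_ancestry_dims)], axis=1
        )
        records.extend(_fit_terms(standardized(y_raw), design, outcome, ASE_TERMS, family="armA"))
    return records


def fit_arm_b(eigengenes: pd.DataFrame, pheno: pd.DataFrame) -> list[RegressionRecord]:
    """ASEs -> module eigengenes, employment as covariate. One record per
    (ME, ASE term); each ASE term's family has one test per module."""
    if not eigengenes.index.equals(pheno.index):
        eigengenes = eigengenes.loc[pheno.index]
    records: list[RegressionRecord] = []
    design = pd.concat([ase_design(pheno), employment_design(pheno)], axis=1)
    for me in eigengenes.columns:
        y = eigengenes[me].to_numpy(dtype=float)
        if y.std(ddof=1) == 0:
            raise ValidationError(f"constant eigengene {me!r}")
        records.extend(_fit_terms(standardized(y), design, me, ASE_TERMS, family="armB"))
    return records


def fit_arm_c(
    eigengenes: pd.DataFrame,
    pheno: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    n_ancestry_dims: int = 4,
) -> list[RegressionRecord]:
    """Module eigengenes -> brain morphometry. One model per (ME, outcome)
    pair with age, ancestry, employment (and ICV for volumes) as
    covariates; the ME is the single predictor of interest."""
    if not eigengenes.index.equals(pheno.index):
        eigengenes = eigengenes.loc[pheno.index]
    if pairs is None:
        pairs = [(me, out) for me in eigengenes.columns for out in MORPHOMETRY_OUTCOMES]
    records: list[RegressionRecord] = []
    for me, outcome in pairs:
        y_raw = pheno[outcome].to_numpy(dtype=float)
        if y_raw.std(ddof=1) == 0:
            raise ValidationError(f"constant outcome {outcome!r}")
        design = covariate_design_arm_a(pheno, outcome, n_ancestry_dims).copy()
        design.insert(0, me, standardized(eigengenes[me]))
        records.extend(_fit_terms(standardized(y_raw), design, outcome, [me], family="armC"))
    return records


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_flags(pvals: Sequence[float], q: float = 0.10, step_up: bool = True) -> np.ndarray:
    """Benjamini-Hochberg significance flags at FDR level ``q``.

    The default is the standard step-up rule: with p-values sorted
    ascending and critical values ``c_k = (k/m) q``, find the largest k
    with ``p_(k) <= c_k`` and flag every test with ``p <= p_(k)`` (ties
    share a flag). ``step_up=False`` applies the literal per-rank
    comparison without the step-up closure, for sensitivity checks.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    crit = (np.arange(1, m + 1) / m) * q
    passed = p[order] <= crit
    if step_up:
        if not passed.any():
            return np.zeros(m, dtype=bool)
        k_star = int(np.max(np.nonzero(passed)[0]))
        return p <= p[order][k_star]
    flags = np.zeros(m, dtype=bool)
    flags[order] = passed
    return flags


def bh_adjust(family: TestFamily, step_up: bool = True) -> TestFamily:
    """Flag the family's records under BH at the family's FDR level."""
    flags = bh_flags([r.p for r in family.records], q=family.q, step_up=step_up)
    family.records = [replace(r, bh_significant=bool(f)) for r, f in zip(family.records, flags)]
    return family


# ---------------------------------------------------------------------------
# mediation candidate gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationCandidate:
    exposure: str
    mediator: str
    outcome: str


def gate_candidates(
    arm_a: Sequence[RegressionRecord],
    arm_b: Sequence[RegressionRecord],
    arm_c: Sequence[RegressionRecord],
    alpha: float = 0.05,
) -> list[MediationCandidate]:
    """Triples passing all three nominal gates: exposure-outcome (Arm A),
    exposure-ME (Arm B) and ME-outcome (Arm C) all below alpha."""
    a_pairs = {(r.term, r.outcome) for r in arm_a if r.p < alpha}
    b_pairs = {(r.term, r.outcome) for r in arm_b if r.p < alpha}  # outcome slot holds the ME
    c_pairs = {(r.term, r.outcome) for r in arm_c if r.p < alpha}  # term slot holds the ME
    out = []
    for term, outcome in sorted(a_pairs):
        for term_b, me in sorted(b_pairs):
            if term_b != term:
                continue
            if (me, outcome) in c_pairs:
                out.append(MediationCandidate(term, me, outcome))
    return out


def records_frame(records: Sequence[RegressionRecord]) -> pd.DataFrame:
    """Tabular view mirroring the outcome/term/beta/SE/t/p report layout."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "term": r.term,
                "beta": r.beta,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "family": r.family,
                "bh_significant": r.bh_significant,
            }
            for r in records
        ]
    )
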