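"""Methylation pre-processing: scale transforms, probe filtering,
leukocyte deconvolution, smoking proxy, and covariate residualization.

The analysis scale throughout the pipeline is the M-value,
``M = log2(beta / (1 - beta))``, which stabilizes the variance of the
bounded beta fraction. Downstream network construction operates on
M-values residualized against technical/biological covariates (age,
leukocyte composition, genomic ancestry, smoking proxy) so that
co-methylation structure reflects shared regulation rather than shared
confounding.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CELL_TYPES, MethylationMatrix, ValidationError, as_cell_proportions

DEFAULT_EPSILON = 1e-6


def beta_to_m(matrix: MethylationMatrix, epsilon: float = DEFAULT_EPSILON) -> MethylationMatrix:
    """Logit2-transform beta values into M-values.

    Beta values are clipped into ``[epsilon, 1 - epsilon]`` first so the
    transform stays finite at the boundaries; interior values are
    untouched.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValidationError("epsilon must lie in (0, 0.5)")
    if matrix.scale != "beta":
        raise ValidationError(f"expected beta-scale input, got {matrix.scale!r}")
    b = matrix.values.clip(lower=epsilon, upper=1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return MethylationMatrix(m, scale="M")


def m_to_beta(m: np.ndarray | pd.DataFrame):
    """Inverse of :func:`beta_to_m` on the open interval: beta = 2^M / (1 + 2^M)."""
    # equivalent to expit(M * ln 2), numerically stable for large |M|
    if isinstance(m, pd.DataFrame):
        from scipy.special import expit

        return pd.DataFrame(expit(m.to_numpy() * np.log(2.0)), index=m.index, columns=m.columns)
    from scipy.special import expit

    return expit(np.asarray(m) * np.log(2.0))


REQUIRED_ANNOTATION_COLUMNS = ("chrom", "cross_reactive", "bloodbrain_p")


def filter_probes(
    matrix: MethylationMatrix,
    annotation: pd.DataFrame,
    bloodbrain_alpha: float = 0.05,
) -> MethylationMatrix:
    """Apply the probe-filter cascade and return the retained submatrix.

    Removes, in order: X/Y-chromosome probes, probes whose id begins with
    ``"rs"`` (SNP control assays), probes flagged as cross-reactive, and
    probes without a nominally significant blood-brain correlation
    (``bloodbrain_p >= bloodbrain_alpha``). The surviving probes keep
    their input order. The blood-brain restriction focuses the analysis
    on loci with some prospect of proxying CNS methylation.
    """
    missing_cols = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing_cols:
        raise ValidationError(f"annotation missing columns: {missing_cols}")
    unannotated = matrix.probe_ids.difference(annotation.index)
    if len(unannotated):
        raise ValidationError(f"probes without annotation rows: {sorted(unannotated)[:10]}")
    ann = annotation.loc[matrix.probe_ids]
    chrom = ann["chrom"].astype(str).str.lower().str.replace("chr", "", regex=False)
    keep = ~chrom.isin(["x", "y"])
    keep &= ~matrix.probe_ids.str.startswith("rs")
    keep &= ann["cross_reactive"].astype(int) == 0
    keep &= ann["bloodbrain_p"] < bloodbrain_alpha
    if not keep.any():
        warnings.warn("probe filter removed every probe", stacklevel=2)
    return MethylationMatrix(matrix.values.loc[keep.to_numpy()], scale=matrix.scale)


def estimate_cell_proportions(
    beta_matrix: MethylationMatrix, reference: pd.DataFrame
) -> pd.DataFrame:
    """Reference-based leukocyte deconvolution (constrained projection).

    For each sample, solves ``min ||R w - y||^2`` over cell-fraction
    vectors ``w`` with ``w >= 0`` and ``sum(w) <= 1``, where ``R`` is the
    reference matrix of cell-type methylation profiles restricted to the
    probes shared with the data. Returns a samples x cell-types fraction
    table over granulocytes, monocytes, B, NK, CD4T and CD8T cells.

    Parameters
    ----------
    beta_matrix
        Beta-scale sample matrix.
    reference
        Probes x cell-types beta matrix with columns named as in
        :data:`methnet.containers.CELL_TYPES`.
    """
    if beta_matrix.scale != "beta":
        raise ValidationError("deconvolution expects beta-scale values")
    missing = [c for c in CELL_TYPES if c not in reference.columns]
    if missing:
        raise ValidationError(f"reference missing cell types: {missing}")
    shared = matrix_reference_overlap(beta_matrix, reference)
    if len(shared) < 50:
        raise ValidationError(f"only {len(shared)} probes shared with reference (need >= 50)")
    R = reference.loc[shared, list(CELL_TYPES)].to_numpy()
    if np.linalg.matrix_rank(R) < len(CELL_TYPES):
        raise ValidationError("rank-deficient cell reference")
    Y = beta_matrix.values.loc[shared].to_numpy()
    out = np.empty((beta_matrix.n_samples, len(CELL_TYPES)))
    for j in range(Y.shape[1]):
        out[j] = _constrained_fractions(R, Y[:, j])
    frame = pd.DataFrame(out, index=beta_matrix.sample_ids, columns=list(CELL_TYPES))
    return as_cell_proportions(frame)


def matrix_reference_overlap(beta_matrix: MethylationMatrix, reference: pd.DataFrame) -> pd.Index:
    return beta_matrix.probe_ids.intersection(reference.index)


def _constrained_fractions(R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nonnegative least squares with a sum <= 1 simplex-box constraint."""
    w0, _ = optimize.nnls(R, y)
    if w0.sum() <= 1.0 + 1e-12:
        return np.clip(w0, 0.0, 1.0)
    res = optimize.minimize(
        lambda w: 0.5 * np.sum((R @ w - y) ** 2),
        x0=w0 / w0.sum(),
        jac=lambda w: R.T @ (R @ w - y),
        bounds=[(0.0, 1.0)] * R.shape[1],
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones_like(w)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, 1.0)


def smoking_score(beta_matrix: MethylationMatrix, effect_table: pd.DataFrame) -> pd.Series:
    """Linear polyepigenetic smoking proxy.

    ``score_s = sum_i effect_i * beta_is`` over the scoring probes present
    in the matrix (canonically the top 26 probes of a smoking EWAS).
    Missing scoring probes are dropped with a warning; an empty overlap is
    an error.
    """
    if "effect" not in effect_table.columns:
        raise ValidationError("effect table needs an 'effect' column indexed by probe id")
    present = effect_table.index.intersection(beta_matrix.probe_ids)
    if len(present) == 0:
        raise ValidationError("no scoring probes present in the matrix")
    if len(present) < len(effect_table):
        warnings.warn(
            f"{len(effect_table) - len(present)} scoring probes absent from matrix", stacklevel=2
        )
    weights = effect_table.loc[present, "effect"]
    betas = beta_matrix.values.loc[present]
    return betas.mul(weights, axis=0).sum(axis=0).rename("smoking_score")


def build_covariate_design(
    pheno: pd.DataFrame,
    cell_proportions: pd.DataFrame,
    smoking: pd.Series,
    n_ancestry_dims: int = 4,
) -> pd.DataFrame:
    """Assemble the residualization design: intercept, age, five leukocyte
    fractions (granulocytes omitted as the complement), ancestry
    dimensions, and the smoking proxy."""
    cells = as_cell_proportions(cell_proportions.loc[pheno.index])
    design = pd.DataFrame({"intercept": 1.0, "age": pheno["age"]}, index=pheno.index)
    for cell in CELL_TYPES[1:]:  # drop granulocytes: fractions are compositional
        design[cell] = cells[cell]
    for k in range(1, n_ancestry_dims + 1):
        design[f"ancestry_{k}"] = pheno[f"ancestry_{k}"]
    design["smoking_score"] = smoking.loc[pheno.index]
    return design


def residualize(m_matrix: MethylationMatrix, design: pd.DataFrame) -> MethylationMatrix:
    """Extract per-probe OLS residuals of M-values on the covariate design.

    Residuals are orthogonal to every design column; with an intercept in
    the design they are mean-zero. The residual matrix is what the
    co-methylation network is built from.
    """
    if m_matrix.scale not in ("M", "residual"):
        raise ValidationError("residualize expects M-scale values")
    X = design.loc[m_matrix.sample_ids].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(f"rank-deficient design: {_collinear_columns(design)}")
    if X.shape[0] <= X.shape[1] + 2:
        raise ValidationError("too few samples for the design")
    Y = m_matrix.values.to_numpy().T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    frame = pd.DataFrame(resid.T, index=m_matrix.probe_ids, columns=m_matrix.sample_ids)
    return MethylationMatrix(frame, scale="residual")


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name design columns implicated in a rank deficiency."""
    bad = []
    X = design.to_numpy(dtype=float)
    base_rank = np.linalg.matrix_rank(X)
    for j, name in enumerate(design.columns):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            bad.append(name)
    return bad


def quantile_normalize(beta_matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the mean order-statistic distribution.

    Each column's k-th smallest value is replaced by the across-sample
    mean of k-th smallest values; ties within a column receive the mean
    of the order statistics they span. With a single sample this is a
    no-op (with a warning).
    """
    if beta_matrix.n_samples < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples", stacklevel=2)
        return beta_matrix
    arr = beta_matrix.values.to_numpy()
    order_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, arr.shape[0] + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, order_means)
    frame = pd.DataFrame(out, index=beta_matrix.probe_ids, columns=beta_matrix.sample_ids)
    return MethylationMatrix(frame, scale=beta_matrix.scale)
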