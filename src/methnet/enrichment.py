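"""Probe-wise exposure EWAS on residualized M-values, probe-to-gene
p-value aggregation, and gene-set over-representation with BH control.

The probe-level screen regresses each residualized probe M-value on the
exposure of interest with the remaining adverse social exposures and
employment as covariates. Probe p-values are collapsed to genes with a
Sidak-corrected minimum (``p_gene = 1 - (1 - min_i p_i)^k`` over the
gene's k probes), which corrects the probes-per-gene bias that plagues
naive min-p aggregation. Gene sets within the configured size bounds are
then tested by the hypergeometric tail of their overlap with the
nominally significant genes, and BH-adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationMatrix, ValidationError
from .screening import ase_design, bh_flags, employment_design


def probewise_ewas(
    residual_matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    exposure_of_interest: str = "ctq",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe linear screen for one exposure.

    All four ASEs enter the design (the exposure of interest plus the
    others and employment as covariates); the returned frame carries the
    exposure term's beta, t and p per probe and a ``significant`` flag at
    ``alpha`` marking the enrichment input set.
    """
    design = pd.concat([ase_design(pheno), employment_design(pheno)], axis=1)
    if exposure_of_interest not in design.columns:
        raise ValidationError(f"unknown exposure {exposure_of_interest!r}")
    X = np.hstack([np.ones((len(pheno), 1)), design.to_numpy(dtype=float)])
    j = 1 + list(design.columns).index(exposure_of_interest)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear or degenerate EWAS design")
    Y = residual_matrix.values.loc[:, pheno.index].to_numpy().T  # samples x probes
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y
    resid = Y - X @ coef
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    beta = coef[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - k)
    frame = pd.DataFrame(
        {"beta": beta, "t": t, "p": p}, index=residual_matrix.probe_ids
    )
    frame["significant"] = frame["p"] < alpha
    return frame


def probes_to_gene_p(probe_ps: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    """Sidak-corrected minimum probe p-value per gene.

    ``p_gene = 1 - (1 - min_i p_i)^k`` for the k measured probes mapped
    to the gene; genes with no measured probe are absent. Monotone:
    lowering any probe p never raises its gene's p.
    """
    if "gene" not in annotation.columns:
        raise ValidationError("annotation needs a 'gene' column")
    genes = annotation.loc[probe_ps.index, "gene"]
    if genes.isna().all() or len(probe_ps) == 0:
        raise ValidationError("empty probe-to-gene mapping")
    grouped = pd.DataFrame({"p": probe_ps, "gene": genes}).dropna().groupby("gene")["p"]
    out = grouped.agg(lambda v: 1.0 - (1.0 - v.min()) ** len(v))
    return out.rename("gene_p")


@dataclass(frozen=True)
class GeneSetResult:
    name: str
    size: int  # measured genes in the set
    overlap: int  # significant measured genes in the set
    p: float
    q: float
    bh_significant: bool
    driver_genes: tuple[str, ...]


def gene_set_test(
    gene_ps: pd.Series,
    gmt_sets: Mapping[str, Sequence[str]],
    min_size: int = 25,
    max_size: int = 1000,
    alpha: float = 0.05,
    q: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric over-representation across gene sets.

    Sets are filtered to ``[min_size, max_size]`` measured genes after
    intersection with the universe of genes that carry a p-value; the
    upper size bound removes uninformative high-level ontology terms.
    The overlap of each surviving set with the genes at ``p < alpha`` is
    scored with the hypergeometric tail; q-values are BH-adjusted over
    tested sets, with step-up flags at FDR ``q``.
    """
    universe = set(gene_ps.index)
    if not universe:
        raise ValidationError("empty gene universe")
    sig = set(gene_ps.index[gene_ps < alpha])
    N, K = len(universe), len(sig)
    rows = []
    for name in sorted(gmt_sets):
        members = sorted(universe.intersection(gmt_sets[name]))
        n = len(members)
        if not min_size <= n <= max_size:
            continue
        overlap = sorted(sig.intersection(members))
        x = len(overlap)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append(
            {"set": name, "size": n, "overlap": x, "p": p, "drivers": ";".join(overlap)}
        )
    if not rows:
        raise ValidationError(
            f"no gene set within [{min_size}, {max_size}] measured genes"
        )
    frame = pd.DataFrame(rows)
    frame["q"] = bh_qvalues(frame["p"].to_numpy())
    frame["bh_significant"] = bh_flags(frame["p"].to_numpy(), q=q)
    return frame.sort_values("p", kind="stable").reset_index(drop=True)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up adjustment)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def read_gmt(path: Path | str) -> dict[str, list[str]]:
    """Load gene sets from a GMT file (name, description, genes...)."""
    import gseapy

    return gseapy.read_gmt(str(path))
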