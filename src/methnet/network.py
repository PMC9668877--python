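"""Weighted co-methylation network: soft-threshold selection, topological
overlap, hierarchical module detection and module eigengenes.

The network follows the weighted correlation-network framework: the
unsigned adjacency ``a_ij = |cor(p_i, p_j)|^power`` raised to the lowest
power at which the connectivity distribution is approximately scale-free
(fit R^2 above a threshold), topological-overlap dissimilarity for
clustering, average-linkage hierarchical clustering with a static tree
cut and a minimum module size, and the first principal component of each
module's standardized probes as the module eigengene (ME).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import MethylationMatrix, ValidationError

#: reporting aliases for module indices, in the spirit of color-named
#: modules; cycled when there are more modules than names
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "maroon", "lightcoral", "indianred",
    "antiquewhite", "coral",
)


def module_color(index: int) -> str:
    """Color alias for a 1-based module index; 0 is the unassigned 'grey'."""
    if index == 0:
        return "grey"
    return MODULE_COLORS[(index - 1) % len(MODULE_COLORS)]


def adjacency(residual_matrix: MethylationMatrix, power: int = 6, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency ``|r|^power`` (unsigned by default).

    The diagonal is set to 0 so that row sums are network connectivities.
    A signed variant ``((1+r)/2)^power`` is available behind the flag.
    """
    if residual_matrix.n_samples < 3:
        raise ValidationError("need >= 3 samples to correlate probes")
    if power < 1:
        raise ValidationError("power must be >= 1")
    X = residual_matrix.values.to_numpy()
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = residual_matrix.probe_ids[sd == 0].tolist()
        raise ValidationError(f"zero-variance probes: {bad[:10]}")
    r = np.corrcoef(X)
    a = ((1.0 + r) / 2.0) ** power if signed else np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)  # symmetrize round-off
    return pd.DataFrame(a, index=residual_matrix.probe_ids, columns=residual_matrix.probe_ids)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> tuple[float, float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Connectivities ``k_i = sum_j a_ij`` are discretized into ``n_bins``
    equal-width bins; the log10 bin frequency is regressed on the log10
    mean connectivity over nonempty bins (the standard scale-free
    topology fit of weighted correlation networks). Returns
    ``(signed_r2, adjusted_r2, mean_k)`` where the signed statistic is
    ``sign(-slope) * R^2`` truncated below at 0 (scale-free topology
    implies a negative slope) and the adjusted statistic applies the
    usual degrees-of-freedom correction to the same fit before signing.
    """
    if adj.shape[0] < 20:
        raise ValidationError("need >= 20 probes for a scale-free fit")
    k = adj.to_numpy().sum(axis=1)
    mean_k = float(k.mean())
    if np.allclose(k, k[0]):
        warnings.warn("all connectivities identical; scale-free R^2 undefined, set to 0", stacklevel=2)
        return 0.0, 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    n = len(k)
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        kb = k[mask].mean()
        if kb <= 0:
            continue
        xs.append(np.log10(kb))
        ys.append(np.log10(mask.sum() / n))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        return 0.0, 0.0, mean_k
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = len(xs) - 2
    adj_r2 = 1.0 - (1.0 - r2) * (len(xs) - 1) / dof if dof > 0 else r2
    sign = 1.0 if slope < 0 else -1.0
    return max(0.0, sign * r2), max(0.0, sign * adj_r2), mean_k


@dataclass
class SoftThresholdScan:
    """Scan table over candidate powers and the chosen soft threshold."""

    table: pd.DataFrame  # power, r2, adjusted_r2, mean_k
    chosen_power: int
    passed: bool  # False when no power cleared r2_min (argmax fallback)
    r2_min: float


def pick_soft_threshold(
    residual_matrix: MethylationMatrix,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_min: float = 0.90,
    use_adjusted: bool = True,
    signed: bool = False,
) -> SoftThresholdScan:
    """Choose the lowest power whose scale-free fit exceeds ``r2_min``.

    When no candidate passes, the power with the best fit is chosen and
    the scan is flagged. Both the signed and the degrees-of-freedom
    adjusted R^2 are tabulated; ``use_adjusted`` selects which one gates.
    """
    if not powers or list(powers) != sorted(powers):
        raise ValidationError("powers must be a nonempty ascending sequence")
    rows = []
    for p in powers:
        r2, adj_r2, mean_k = scale_free_fit(adjacency(residual_matrix, power=p, signed=signed))
        rows.append({"power": p, "r2": r2, "adjusted_r2": adj_r2, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    crit = table["adjusted_r2"] if use_adjusted else table["r2"]
    passing = table.loc[crit > r2_min, "power"]
    if len(passing):
        return SoftThresholdScan(table, int(passing.iloc[0]), True, r2_min)
    fallback = int(table.loc[crit.idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached R^2 > {r2_min}; falling back to argmax power {fallback}",
        stacklevel=2,
    )
    return SoftThresholdScan(table, fallback, False, r2_min)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological-overlap dissimilarity ``1 - TOM``.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj``; two probes overlap strongly when they are
    connected and share neighbors. The diagonal dissimilarity is 0.
    """
    A = adj.to_numpy()
    if A.size and (A.min() < 0 or A.max() > 1):
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise ValidationError("adjacency diagonal must be 0")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Probe -> module assignment with per-module eigengenes.

    ``labels`` maps probes to 1..K (0 = unassigned); ``eigengenes`` holds
    per-sample ME scores (unit variance, one column per module);
    ``variance_explained`` is the fraction of the module's standardized
    probe variance captured by its first principal component.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    variance_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def n_modules(self) -> int:
        return int((np.unique(self.labels) > 0).sum())

    def color_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_index": self.labels,
                "module_color_alias": [module_color(v) for v in self.labels],
            },
            index=self.labels.index,
        )


def cluster_modules(
    dissimilarity: pd.DataFrame,
    min_size: int = 10,
    cut_height: float | None = None,
    cut_fraction: float = 0.95,
) -> ModuleSet:
    """Average-linkage clustering of the TOM dissimilarity with a static cut.

    The tree is cut at ``cut_height`` (default: ``cut_fraction`` of the
    maximum merge height); clusters below ``min_size`` are unassigned
    (label 0) and survivors are relabeled 1..K by decreasing size.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    D = dissimilarity.to_numpy()
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    height = float(Z[:, 2].max()) if len(Z) else 0.0
    cut = cut_height if cut_height is not None else cut_fraction * height
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = _prune_and_relabel(raw, min_size)
    return ModuleSet(pd.Series(labels, index=dissimilarity.index, name="module"))


def _prune_and_relabel(raw: np.ndarray, min_size: int) -> np.ndarray:
    out = np.zeros_like(raw)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].sort_values(ascending=False)
    for new, (old, _) in enumerate(keep.items(), start=1):
        out[raw == old] = new
    return out


def module_eigengenes(residual_matrix: MethylationMatrix, labels: pd.Series) -> ModuleSet:
    """First principal component of each module's standardized probes.

    Probes are z-scored across samples; the ME is the leading left
    singular vector of the samples x probes block, sign-aligned to
    correlate nonnegatively with the module's mean probe profile and
    scaled to unit variance. ``variance_explained`` is the leading
    squared singular value over the total.
    """
    labels = labels.loc[residual_matrix.probe_ids]
    scores: dict[str, np.ndarray] = {}
    varex: dict[str, float] = {}
    for mod in sorted(set(labels[labels > 0])):
        probes = labels.index[labels == mod]
        if len(probes) < 2:
            raise ValidationError(f"module {mod} has fewer than 2 probes")
        X = residual_matrix.values.loc[probes].to_numpy()
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValidationError(f"constant probe in module {mod}")
        Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        U, S, Vt = np.linalg.svd(Xz.T, full_matrices=False)  # samples x probes
        me = U[:, 0] * S[0]
        mean_profile = Xz.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me = me / me.std(ddof=1)
        name = f"ME{mod}"
        scores[name] = me
        varex[name] = float(S[0] ** 2 / np.sum(S**2))
    eigengenes = pd.DataFrame(scores, index=residual_matrix.sample_ids)
    return ModuleSet(labels, eigengenes, pd.Series(varex, dtype=float))


def build_network_modules(
    residual_matrix: MethylationMatrix,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_min: float = 0.90,
    min_size: int = 10,
    cut_height: float | None = None,
    cut_fraction: float = 0.95,
    signed: bool = False,
    power: int | None = None,
) -> tuple[SoftThresholdScan, ModuleSet]:
    """Full chain: soft threshold -> adjacency -> TOM -> modules -> MEs.

    ``power`` overrides the scan with a fixed soft threshold; the scan
    is then skipped and the table holds only that power's fit.
    """
    if power is not None:
        r2, adj_r2, mean_k = scale_free_fit(adjacency(residual_matrix, power=power, signed=signed))
        table = pd.DataFrame(
            [{"power": power, "r2": r2, "adjusted_r2": adj_r2, "mean_k": mean_k}]
        )
        scan = SoftThresholdScan(table, int(power), adj_r2 > r2_min, r2_min)
    else:
        scan = pick_soft_threshold(residual_matrix, powers=powers, r2_min=r2_min, signed=signed)
    adj = adjacency(residual_matrix, power=scan.chosen_power, signed=signed)
    d = tom_dissimilarity(adj)
    modules = cluster_modules(d, min_size=min_size, cut_height=cut_height, cut_fraction=cut_fraction)
    if (modules.labels > 0).any():
        modules = module_eigengenes(residual_matrix, modules.labels)
    return scan, modules
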