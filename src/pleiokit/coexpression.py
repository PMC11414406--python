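"""Coexpression module detection over per-strain mean expression profiles.

The pipeline mirrors weighted gene coexpression network analysis: pairwise
correlation across strains -> soft-thresholded adjacency ``|cor|^power`` ->
topological overlap similarity -> average-linkage hierarchical clustering of
the TOM dissimilarity -> a static tree cut with a minimum module size floor
-> merging of modules whose eigengenes are nearly collinear.  Genes that
fail the cut (or have zero variance) receive module id 0 ("unassigned") and
are ignored by downstream pleiotropy counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringParams:
    """Module-detection parameters.

    ``min_module_size`` and ``merge_cut_height`` default to the study's
    stated clustering parameters (10 and 0.1).  ``soft_power`` defaults to
    6, the conventional choice for unsigned networks at a few dozen
    samples; ``"auto"`` selects it by the scale-free topology criterion
    instead, which is less stable on small strain panels.  ``cut_height``
    defaults to 0.98 x the tallest merge, which on block-structured data
    separates planted modules from the near-unit plateau of
    unrelated-gene merges.
    """

    min_module_size: int = 10
    merge_cut_height: float = 0.1
    soft_power: int | str = 6
    cut_height: float | str = "auto"
    signed_hybrid: bool = False

    def __post_init__(self) -> None:
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0, 1)")


@dataclass
class ModuleAssignment:
    """Gene -> module id map; id 0 means unassigned.

    ``eigengenes`` holds one per-strain score column per module id.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame

    @property
    def module_count(self) -> int:
        return int((np.unique(self.labels) > 0).sum())

    def members(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]


def _adjacency(expr: pd.DataFrame, power: int, signed_hybrid: bool) -> np.ndarray:
    cor = np.corrcoef(expr.to_numpy(float))
    if signed_hybrid:
        base = np.clip(cor, 0.0, 1.0)
    else:
        base = np.abs(cor)
    adj = base**power
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins the connectivities, regresses log10 frequency on log10 mean
    connectivity per occupied bin, and returns ``(r_squared, slope)``.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = ((ys - fitted) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
    signed_hybrid: bool = False,
) -> int:
    """Smallest power whose signed scale-free fit reaches ``target_r2``.

    The signed fit index is ``-sign(slope) * R^2`` (a scale-free degree
    distribution has a negative log-log slope).  If no power reaches the
    target, the power maximizing the index is returned.  Deterministic.
    """
    mat = expr.to_numpy(float)
    if mat.shape[0] < 2 or np.allclose(mat.std(axis=1), 0):
        raise ValueError("expression matrix is constant; soft threshold undefined")
    best_power, best_index = None, -np.inf
    for power in powers:
        adj = _adjacency(expr, power, signed_hybrid)
        r2, slope = scale_free_fit(adj.sum(axis=0))
        index = -np.sign(slope) * r2
        if index >= target_r2:
            return int(power)
        if index > best_index:
            best_index, best_power = index, int(power)
    return best_power


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    ``omega_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L = A @ A`` and connectivity ``k = A.sum``; the diagonal is 1.
    """
    a = np.asarray(adjacency, float)
    L = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(expr: pd.DataFrame, member_genes) -> pd.Series:
    """First principal component of the standardized member submatrix.

    The per-strain score vector is sign-oriented so its correlation with the
    mean member profile is nonnegative.
    """
    members = list(member_genes)
    if len(members) < 2:
        raise ValueError("an eigengene needs at least 2 member genes")
    sub = expr.loc[members].to_numpy(float)
    sd = sub.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("rank-0 member submatrix; eigengene undefined")
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if float(eig @ mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def _merge_close_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < cutoff.

    Dissimilarity is 1 - cor(eigengene_i, eigengene_j).  Idempotent: once no
    pair is below the cutoff, re-running changes nothing.
    """
    labels = labels.copy()
    while True:
        ids = sorted(set(labels[labels > 0]))
        if len(ids) < 2:
            return labels
        eigs = {m: module_eigengene(expr, labels.index[labels == m]) for m in ids}
        best_pair, best_diss = None, np.inf
        for i, m1 in enumerate(ids):
            for m2 in ids[i + 1 :]:
                cor = float(np.corrcoef(eigs[m1], eigs[m2])[0, 1])
                diss = 1.0 - cor
                if diss < best_diss:
                    best_diss, best_pair = diss, (m1, m2)
        if best_diss >= merge_cut_height:
            return labels
        m1, m2 = best_pair
        labels[labels == m2] = m1


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels > 0].value_counts()
    # sort by decreasing size, ties by old id for determinism
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping)


def detect_modules(expr: pd.DataFrame, params: ClusteringParams = ClusteringParams()) -> ModuleAssignment:
    """Cluster genes into coexpression modules from a gene x strain matrix.

    Zero-variance genes are dropped to id 0 (logged).  Clusters below
    ``min_module_size`` after the static cut are unassigned.  Modules whose
    eigengene dissimilarity falls below ``merge_cut_height`` are merged, and
    final ids are renumbered 1..K by decreasing size.
    """
    if expr.shape[0] < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    mat = expr.to_numpy(float)
    variable = mat.std(axis=1) > 0
    n_constant = int((~variable).sum())
    if n_constant:
        logger.info("dropping %d zero-variance genes to module 0", n_constant)
    used = expr.loc[variable]
    labels = pd.Series(0, index=expr.index, dtype=int)

    if used.shape[0] >= params.min_module_size:
        power = (
            pick_soft_threshold(used, signed_hybrid=params.signed_hybrid)
            if params.soft_power == "auto"
            else int(params.soft_power)
        )
        adj = _adjacency(used, power, params.signed_hybrid)
        diss = 1.0 - topological_overlap(adj)
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(diss, checks=False), method="average")
        heights = Z[:, 2]
        cut = (
            0.98 * heights.max() if params.cut_height == "auto" else float(params.cut_height)
        )
        raw = fcluster(Z, t=cut, criterion="distance")
        raw_series = pd.Series(raw, index=used.index)
        sizes = raw_series.value_counts()
        keep_ids = sizes.index[sizes >= params.min_module_size]
        assigned = raw_series.where(raw_series.isin(keep_ids), 0)
        labels.loc[used.index] = assigned
        labels = _merge_close_modules(expr, labels, params.merge_cut_height)
    labels = _relabel_by_size(labels)

    eig_cols = {}
    for m in sorted(set(labels[labels > 0])):
        eig_cols[m] = module_eigengene(expr, labels.index[labels == m])
    eigengenes = pd.DataFrame(eig_cols) if eig_cols else pd.DataFrame(index=expr.columns)
    return ModuleAssignment(labels=labels, eigengenes=eigengenes)
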