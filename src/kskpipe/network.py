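"""Signed soft-threshold co-expression network and module analysis.

Edge weights follow the signed weighted-network convention:
``w_ij = ((1 + r_ij) / 2) ** beta`` with Pearson r and soft power beta
(default 5), so anticorrelated genes get weight near 0 rather than near 1.
The soft power is checked (or chosen) by the scale-free topology criterion:
the squared correlation of log10(mean connectivity) versus log10(frequency)
over equal-width connectivity bins must exceed 0.6.

Modules come from average-linkage hierarchical clustering of the topological
overlap dissimilarity (1 - TOM) with a static height cut and a minimum
module size of 30; clusters below the minimum are left unassigned (module
0) and modules are renumbered by decreasing size. The static cut is a
deliberate simplification of dynamic dendrogram cutting: the claims this
package supports concern enrichment and thresholding, not parity with any
particular module-detection heuristic.

The visualised subnetwork keeps only edges with weight strictly greater
than 0.43; hubs are nodes with strictly more than 50 connections in that
thresholded graph. Module over-representation of a DEG set uses a one-sided
Fisher exact test computed in log space, so p-values far below 1e-300
remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    weights: np.ndarray  # symmetric, [0, 1], unit diagonal
    beta: float = 5.0
    signed: bool = True


@dataclass
class ModuleAssignment:
    assignments: dict[str, int]  # 0 = unassigned
    min_module_size: int = 30

    def module_genes(self, module_id: int) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module_id]

    def n_modules(self) -> int:
        return len({m for m in self.assignments.values() if m > 0})


@dataclass
class EnrichmentResult:
    module_id: int
    overlap: int
    module_size: int
    deg_size: int
    universe_size: int
    p: float  # may underflow to 0.0 for extreme tables; log10_p stays finite
    log10_p: float


def signed_adjacency(
    expression: pd.DataFrame, beta: float = 5.0
) -> CoexpressionNetwork:
    """Signed adjacency ``((1 + r) / 2) ** beta`` over genes (rows).

    Requires at least 3 samples and positive variance for every gene; a
    zero-variance gene is reported by name rather than propagating NaNs.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 samples per gene")
    values = expression.to_numpy(dtype=float)
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = list(expression.index[sds == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    corr = np.corrcoef(values)
    weights = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(weights, 1.0)
    weights = np.clip((weights + weights.T) / 2.0, 0.0, 1.0)
    return CoexpressionNetwork(list(expression.index), weights, beta=beta)


def connectivity(network: CoexpressionNetwork) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} w_ij."""
    return network.weights.sum(axis=1) - 1.0


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free fit index from a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; the index is
    the squared Pearson correlation of log10(mean k per bin) against
    log10(bin frequency) over non-empty bins. Returns (R^2, mean k).
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all values identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0 and k[mask].mean() > 0:
            log_k.append(np.log10(k[mask].mean()))
            log_f.append(np.log10(mask.sum()))
    if len(log_k) < 2:
        raise ValueError("fewer than 2 non-empty connectivity bins")
    r = stats.pearsonr(log_k, log_f).statistic
    return float(r**2), float(k.mean())


def scale_free_fit(network: CoexpressionNetwork, n_bins: int = 10) -> tuple[float, float]:
    return scale_free_r2(connectivity(network), n_bins)


def pick_soft_threshold(
    expression: pd.DataFrame,
    betas: tuple[float, ...] = tuple(range(1, 21)),
    r2_min: float = 0.6,
    n_bins: int = 10,
) -> tuple[float, float]:
    """Smallest beta in the sweep whose scale-free fit exceeds ``r2_min``."""
    last = (np.nan, np.nan)
    for beta in betas:
        net = signed_adjacency(expression, beta=beta)
        r2, _ = scale_free_fit(net, n_bins)
        last = (beta, r2)
        if r2 > r2_min:
            return float(beta), float(r2)
    raise ValueError(f"no beta in sweep reached R^2 > {r2_min} (last: {last})")


def tom_similarity(network: CoexpressionNetwork) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u w_iu w_uj + w_ij) / (min(k_i, k_j) + 1 - w_ij) with the
    shared-neighbour sum over u != i, j and k the whole-network
    connectivity; TOM_ii = 1. For two genes with no shared neighbours this
    reduces to w_ij itself.
    """
    w = network.weights
    k = connectivity(network)
    shared = w @ w - 2.0 * w  # removes the u=i and u=j terms (unit diagonal)
    numer = shared + w
    denom = np.minimum.outer(k, k) + 1.0 - w
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    network: CoexpressionNetwork,
    min_module_size: int = 30,
    cut_height: float = 0.8,
) -> ModuleAssignment:
    """Static-height cut of the average-linkage 1 - TOM dendrogram.

    Clusters smaller than ``min_module_size`` become module 0 (unassigned);
    surviving modules are renumbered 1, 2, ... by decreasing size.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must be in (0, 1]")
    diss = 1.0 - tom_similarity(network)
    condensed = squareform(diss, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].sort_values(ascending=False)
    relabel = {old: i + 1 for i, old in enumerate(keep.index)}
    assignments = {
        g: relabel.get(raw[i], 0) for i, g in enumerate(network.genes)
    }
    return ModuleAssignment(assignments, min_module_size)


def edge_list(network: CoexpressionNetwork, weight_min: float = 0.43) -> pd.DataFrame:
    """Edges (i < j) with weight strictly greater than ``weight_min``,
    sorted by descending weight (ties by gene pair)."""
    w = network.weights
    iu, ju = np.triu_indices(len(network.genes), k=1)
    mask = w[iu, ju] > weight_min
    rows = pd.DataFrame(
        {
            "gene_a": [network.genes[i] for i in iu[mask]],
            "gene_b": [network.genes[j] for j in ju[mask]],
            "weight": w[iu[mask], ju[mask]],
        }
    )
    if rows.empty:
        return rows
    return rows.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True], ignore_index=True
    )


def hub_genes(edges: pd.DataFrame, min_connections: int = 50) -> list[str]:
    """Genes with strictly more than ``min_connections`` thresholded edges."""
    if edges.empty:
        return []
    degree = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
    return sorted(degree.index[degree > min_connections])


def fisher_enrichment_logp(
    overlap: int, module_size: int, deg_size: int, universe_size: int
) -> float:
    """Natural-log one-sided (over-representation) Fisher p for a 2x2 table.

    ln P(X >= overlap) for hypergeometric X ~ (universe, deg, module),
    computed as a log-sum-exp over hypergeometric log-pmf terms so extreme
    tables keep a finite log p even when p underflows double precision.
    With zero overlap the one-sided p is 1 by construction.
    """
    if universe_size < 1:
        raise ValueError("empty universe")
    if not (0 <= overlap <= min(module_size, deg_size)):
        raise ValueError("overlap exceeds module or DEG-set size")
    xs = np.arange(overlap, min(module_size, deg_size) + 1)
    if len(xs) == 0:
        return 0.0
    logpmf = stats.hypergeom.logpmf(xs, universe_size, deg_size, module_size)
    return min(0.0, float(special.logsumexp(logpmf)))


def module_enrichment(
    module_genes: set[str] | list[str],
    deg_set: set[str] | list[str],
    universe: set[str] | list[str],
    module_id: int = 0,
) -> EnrichmentResult:
    """One-sided Fisher over-representation of a DEG set in a module.

    See :func:`fisher_enrichment_logp` for the log-space tail computation.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    deg = set(deg_set)
    if not module <= universe or not deg <= universe:
        raise ValueError("module and DEG set must be subsets of the universe")
    n, m, d = len(universe), len(module), len(deg)
    a = len(module & deg)
    log_p = fisher_enrichment_logp(a, m, d, n)
    return EnrichmentResult(
        module_id, a, m, d, n, float(np.exp(log_p)), float(log_p / np.log(10.0))
    )
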