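"""Interaction-profile clustering and gene-set enrichment.

Genes with strong interactions in either screen are assembled into
fixed-order profile vectors (by default the 15 perturbation columns A-O:
the misfolded-allele screen, the wild-type screen, the control-media
growth defect, and twelve gene-drug conditions) and clustered by
recursive expectation-maximization (REMc): a Gaussian-mixture EM fit
picks the number of clusters objectively by BIC, and each resulting
cluster is re-clustered until the criterion favours a single component or
the cluster is too small.  Members of each cluster are then ordered by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage) for heat-map display, and clusters are scored for gene-set
enrichment with exact hypergeometric tests plus a permutation z-score of
aggregate enrichment ("GOid_z-style").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.stats import false_discovery_control, hypergeom
from sklearn.mixture import GaussianMixture

from .interaction import NO_INTERACTION, InteractionResult, Thresholds, classify

#: default perturbation-column schema (misfolded-allele screen, wild-type
#: screen, control growth, 12 gene-drug conditions)
PROFILE_COLUMNS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNO")


@dataclass(frozen=True)
class InteractionProfile:
    """Per-gene interaction vector over the perturbation columns; masked
    entries are missing and imputed to column medians before clustering."""

    gene_id: str
    values: np.ndarray
    mask: np.ndarray  # True where missing

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError(f"{self.gene_id}: values and mask must match 1-D")
        if np.any(~np.isfinite(v) & ~m):
            raise ValueError(f"{self.gene_id}: unmasked values must be finite")


def make_profile(
    gene_id: str, values: Sequence[float], columns: Sequence[str] = PROFILE_COLUMNS
) -> InteractionProfile:
    v = np.asarray(values, dtype=float)
    if v.size != len(columns):
        raise ValueError(
            f"{gene_id}: expected {len(columns)} columns, got {v.size}"
        )
    return InteractionProfile(gene_id, v, ~np.isfinite(v))


@dataclass
class ClusterNode:
    """One node of the REMc tree.  ``name`` encodes round and lineage
    ("2-0.1-1" = round 2, child 1 of round-1 cluster 0.1); children
    partition the members."""

    name: str
    members: list[str]
    log_likelihood: float
    children: list["ClusterNode"] = field(default_factory=list)

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out: list[ClusterNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass(frozen=True)
class REMcConfig:
    """REMc settings: candidate component counts 1..k_max, seeded EM
    restarts per k, and the minimum cluster size below which recursion
    stops."""

    k_max: int = 6
    n_restarts: int = 10
    min_cluster: int = 9
    max_iter: int = 500
    # variance floor per dimension; keeps EM away from degenerate
    # single-point components that otherwise make BIC over-split
    reg_covar: float = 1e-2
    seed: int = 0


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_size: int
    cluster_size: int
    overlap: int
    p_value: float
    p_adjusted: float


def select_genes(
    primary: Mapping[str, InteractionResult],
    wildtype: Mapping[str, InteractionResult],
    primary_thresholds: Thresholds,
    wildtype_thresholds: Thresholds,
) -> set[str]:
    """Union of genes passing either screen's strict-inequality cuts;
    tiered no-growth enhancers (unscoreable INT) pass as well."""
    selected: set[str] = set()
    for results, th in (
        (primary, primary_thresholds),
        (wildtype, wildtype_thresholds),
    ):
        for gene, res in results.items():
            if classify(res, th) != NO_INTERACTION:
                selected.add(gene)
    return selected


def impute_matrix(profiles: Sequence[InteractionProfile]) -> np.ndarray:
    """Stack profiles into a matrix with masked entries imputed to column
    medians (a column that is entirely missing imputes to 0)."""
    X = np.vstack([p.values for p in profiles]).astype(float)
    M = np.vstack([p.mask for p in profiles])
    X[M] = np.nan
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    idx = np.nonzero(M)
    X[idx] = med[idx[1]]
    return X


def _fit_best_gmm(
    X: np.ndarray, cfg: REMcConfig, seed: int
) -> tuple[GaussianMixture, int]:
    """Fit diagonal-covariance mixtures for k = 1..k_max and return the
    BIC-best model."""
    best: GaussianMixture | None = None
    best_bic = math.inf
    best_k = 1
    # entertain no more components than could each hold a minimum-size
    # cluster; stops BIC chasing singletons in small nodes
    k_cap = max(1, min(cfg.k_max, X.shape[0] // max(cfg.min_cluster, 1)))
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=cfg.n_restarts,
            max_iter=cfg.max_iter,
            reg_covar=cfg.reg_covar,
            random_state=seed,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best, best_bic, best_k = gm, bic, k
    assert best is not None
    return best, best_k


def remc(
    profiles: Sequence[InteractionProfile], cfg: REMcConfig = REMcConfig()
) -> ClusterNode:
    """Recursive EM clustering of interaction profiles.

    Deterministic for a fixed ``cfg.seed``: every EM fit derives its
    random state from the seed and the node's lineage.
    """
    if len(profiles) < 2:
        ids = [p.gene_id for p in profiles]
        return ClusterNode("0", ids, 0.0)
    X = impute_matrix(profiles)
    ids = [p.gene_id for p in profiles]
    root = ClusterNode("0", list(ids), 0.0)
    _remc_split(X, np.array(ids, dtype=object), root, ("0",), 1, cfg)
    return root


def _node_seed(seed: int, lineage: tuple[str, ...]) -> int:
    ss = np.random.SeedSequence([seed] + [int(i) for tok in lineage for i in tok.split(".")])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _remc_split(
    X: np.ndarray,
    ids: np.ndarray,
    node: ClusterNode,
    lineage: tuple[str, ...],
    round_no: int,
    cfg: REMcConfig,
) -> None:
    if X.shape[0] < max(2, cfg.min_cluster):
        return
    gm, k = _fit_best_gmm(X, cfg, _node_seed(cfg.seed, lineage))
    node.log_likelihood = float(gm.score_samples(X).sum())
    if k == 1:
        return
    labels = gm.predict(X)
    logp = gm.score_samples(X)
    lineage_str = ".".join(lineage)
    for j in range(k):
        pick = labels == j
        if not pick.any():
            continue
        child = ClusterNode(
            f"{round_no}-{lineage_str}-{j}",
            list(ids[pick]),
            float(logp[pick].sum()),
        )
        node.children.append(child)
        _remc_split(X[pick], ids[pick], child, lineage + (str(j),), round_no + 1, cfg)


def hclust_order(
    members: Sequence[str], profiles: Mapping[str, InteractionProfile]
) -> tuple[list[str], np.ndarray | None]:
    """Order cluster members for display by agglomerative clustering
    (Euclidean distance, complete linkage); returns (leaf order, linkage
    matrix).  A single member yields itself and no dendrogram."""
    if len(members) == 0:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return list(members), None
    X = impute_matrix([profiles[m] for m in members])
    Z = linkage(X, method="complete", metric="euclidean")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return [members[i] for i in order], Z


def hypergeom_pvalue(universe_size: int, term_size: int, cluster_size: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability of seeing >= overlap term
    genes in a random cluster of this size."""
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, cluster_size))


def enrichment(
    members: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[list[EnrichmentResult], float]:
    """Per-term hypergeometric enrichment of a cluster plus an aggregate
    permutation z-score.

    The aggregate statistic is the summed -log10 p over terms; its null
    distribution comes from ``n_permutations`` random same-size clusters
    drawn from the universe, and the z-score ("GOid_z-style") measures how
    much more functional annotation the cluster carries than chance.
    """
    members = set(members)
    universe = sorted(set(universe))
    if not members or not universe:
        raise ValueError("cluster and universe must be non-empty")
    if not members <= set(universe):
        raise ValueError("cluster members must lie within the universe")
    M = len(universe)
    n = len(members)

    def term_pvalues(cluster: set[str]) -> list[tuple[str, int, int, float]]:
        rows = []
        for term, genes in gene_sets.items():
            genes_in_universe = genes & set(universe)
            k = len(genes_in_universe & cluster)
            p = hypergeom_pvalue(M, len(genes_in_universe), len(cluster), k)
            rows.append((term, len(genes_in_universe), k, p))
        return rows

    observed = term_pvalues(members)
    pvals = np.array([p for *_, p in observed])
    padj = false_discovery_control(pvals, method="bh") if len(pvals) else pvals
    results = [
        EnrichmentResult(term, size, n, k, float(p), float(q))
        for (term, size, k, p), q in zip(observed, padj)
    ]

    def aggregate(cluster: set[str]) -> float:
        return float(sum(-math.log10(p) for *_, p in term_pvalues(cluster)))

    obs_stat = aggregate(members)
    rng = np.random.default_rng(seed)
    null = np.array([
        aggregate(set(rng.choice(universe, size=n, replace=False)))
        for _ in range(n_permutations)
    ])
    sd = float(null.std(ddof=1))
    z = (obs_stat - float(null.mean())) / sd if sd > 0 else 0.0
    return results, float(z)


def cluster_summary(
    root: ClusterNode,
    profiles: Mapping[str, InteractionProfile],
    gene_sets: Mapping[str, set[str]] | None = None,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-leaf summary table: id, size, log-likelihood, aggregate z and
    enriched-term count (when gene sets are supplied)."""
    rows = []
    for leaf in root.leaves():
        row: dict[str, object] = {
            "cluster": leaf.name,
            "size": len(leaf.members),
            "log_likelihood": leaf.log_likelihood,
        }
        if gene_sets is not None and universe is not None and leaf.members:
            results, z = enrichment(
                leaf.members, gene_sets, universe,
                n_permutations=n_permutations, seed=seed,
            )
            row["aggregate_z"] = z
            row["n_enriched_terms"] = sum(r.p_adjusted < alpha for r in results)
        rows.append(row)
    return pd.DataFrame(rows)
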