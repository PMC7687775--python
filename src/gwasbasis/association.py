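"""Downstream analyses of projected traits.

Three follow-ups guard and extend a significant projection:

* a *consistency* check — a weighted Spearman rank correlation between the
  projected trait's shrunk effects and the component's rotation entries on
  LD-pruned driver SNPs, with permutation significance, to ensure a signal
  reflects many small concordant effects rather than one outlier SNP in LD
  with something large;
* *subset-selected FDR* — Benjamini-Hochberg run only within the driver
  SNPs of the trait's significant components, boosting power for small
  GWAS, followed by greedy LD pruning of the ranked hits;
* agglomerative *clustering* of traits by Euclidean distance between their
  delta vectors under Ward's criterion (the Ward.D2 variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import norm, rankdata

from gwasbasis.basis import Basis
from gwasbasis.harmonise import ReferencePanel, SummaryStats
from gwasbasis.projection import Projection, fdr_adjust
from gwasbasis.shrinkage import ShrinkageWeights, shrink


def weighted_spearman(x, y, w=None) -> float:
    """Weighted Spearman rank correlation.

    Both vectors are converted to average ranks (ties share their mean
    rank), then correlated by weighted Pearson with normalised weights.
    With equal weights this reduces exactly to the ordinary Spearman rho.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative, not all zero")
    w = w / w.sum()
    rx = rankdata(x)
    ry = rankdata(y)
    mx, my = w @ rx, w @ ry
    dx, dy = rx - mx, ry - my
    vx, vy = w @ dx**2, w @ dy**2
    if vx <= 0 or vy <= 0:
        raise ValueError("rank variance is zero; correlation undefined")
    return float((w @ (dx * dy)) / np.sqrt(vx * vy))


def _pairwise_r2(panel: ReferencePanel, ids: pd.Index) -> np.ndarray:
    """Squared LD correlation between the given variants (0 across blocks)."""
    sub = panel.subset(ids)
    order = sub.index.get_indexer(ids)
    if np.any(order < 0):
        raise ValueError("variants missing from panel")
    n = len(ids)
    r2 = np.zeros((n, n))
    inv = np.empty(n, int)
    inv[order] = np.arange(n)
    for blk, rows in sub.block_slices().items():
        r = sub.ld_for(blk)
        pos = inv[rows]
        r2[np.ix_(pos, pos)] = r**2
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(panel: ReferencePanel, ids: pd.Index, r2_max: float,
             inclusive: bool = False) -> pd.Index:
    """Greedy LD pruning in the given priority order.

    Walks ``ids`` front to back, keeping a variant only if its r-squared
    with every already-kept variant is below ``r2_max`` (or at most
    ``r2_max`` when ``inclusive``); the first-ranked member of each LD
    clique survives.
    """
    r2 = _pairwise_r2(panel, ids)
    kept: list[int] = []
    for i in range(len(ids)):
        if inclusive:
            ok = all(r2[i, j] <= r2_max for j in kept)
        else:
            ok = all(r2[i, j] < r2_max for j in kept)
        if ok:
            kept.append(i)
    return ids[kept]


@dataclass
class ConsistencyResult:
    trait_id: str
    component: int
    rho: float
    p_perm: float
    n_snps: int
    n_perm: int


def consistency_test(
    ss: SummaryStats,
    basis: Basis,
    component: int,
    panel: ReferencePanel,
    r2_max: float = 0.01,
    n_perm: int = 10_000,
    seed: int | None = None,
    weights: ShrinkageWeights | None = None,
) -> ConsistencyResult:
    """Weighted Spearman consistency of a projection on one component.

    Driver SNPs of ``component`` (0-based) are pruned to pairwise
    r-squared < ``r2_max``, greedily in decreasing |Q_ik|. rho correlates
    the trait's shrunk effects with the rotation entries over the pruned
    set, weighting by w/sigma_MAF. Significance permutes the trait's values
    (two-sided): p = (1 + #{|rho_perm| >= |rho|}) / (n_perm + 1).
    """
    drivers = basis.driver_snps(component)
    qk = pd.Series(basis.rotation[:, component], index=basis.variant_index)
    drivers = drivers[np.argsort(-np.abs(qk.loc[drivers].to_numpy()),
                                 kind="stable")]
    pruned = ld_prune(panel, drivers, r2_max)
    if len(pruned) < 3:
        raise ValueError(
            f"component {component}: only {len(pruned)} driver SNPs left "
            f"after LD pruning at r2 < {r2_max}")
    if weights is None:
        weights = ShrinkageWeights(index=basis.variant_index,
                                   sigma_maf=basis.sigma_maf, w=basis.w,
                                   prior=basis.prior)
    gamma = shrink(ss, weights, basis.mode)
    pos = basis.variant_index.get_indexer(pruned)
    x = gamma.to_numpy(float)[pos]
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{ss.trait_id}: missing effects at driver SNPs")
    y = basis.rotation[pos, component]
    wgt = basis.w[pos] / basis.sigma_maf[pos]
    rho = weighted_spearman(x, y, wgt)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rho_p = weighted_spearman(rng.permutation(x), y, wgt)
        if abs(rho_p) >= abs(rho):
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return ConsistencyResult(trait_id=ss.trait_id, component=component,
                             rho=rho, p_perm=p_perm, n_snps=len(pruned),
                             n_perm=n_perm)


def subset_selected_fdr(
    ss: SummaryStats,
    basis: Basis,
    significant_components: Sequence[int],
    panel: ReferencePanel,
    r2_prune: float = 0.1,
) -> pd.DataFrame:
    """FDR restricted to driver SNPs of significant components, LD-pruned.

    GWAS p-values (two-sided, from beta/se) are computed at the union of
    driver SNPs over the trait's significant components and BH-adjusted
    within that subset only. SNPs are then ranked by increasing ssFDR (ties
    by raw p, then variant key) and greedily pruned so no kept SNP has
    r-squared > ``r2_prune`` with a higher-placed one; pruned SNPs are
    flagged rather than removed from the table.
    """
    if len(significant_components) == 0:
        raise ValueError("trait has no significant components")
    union = pd.Index([], name="variant")
    comp_of: dict[str, list[int]] = {}
    for k in significant_components:
        dk = basis.driver_snps(k)
        union = union.union(dk, sort=False)
        for v in dk:
            comp_of.setdefault(v, []).append(int(k))
    union = basis.variant_index[basis.variant_index.isin(union)]
    beta = ss.data["beta"].reindex(union)
    se = ss.data["se"].reindex(union)
    ok = beta.notna() & se.notna()
    union = union[ok.to_numpy()]
    z = (beta[ok] / se[ok]).to_numpy(float)
    p = 2.0 * norm.sf(np.abs(z))
    ssfdr = fdr_adjust(p)
    tab = pd.DataFrame(
        {
            "trait": ss.trait_id,
            "variant": union,
            "components": [",".join(map(str, sorted(comp_of[v]))) for v in union],
            "p_gwas": p,
            "ssfdr": ssfdr,
        }
    )
    tab = tab.sort_values(["ssfdr", "p_gwas", "variant"],
                          kind="stable").reset_index(drop=True)
    # the rule is "delete when r2 > r2_prune", i.e. ties at the bound survive
    kept_ids = set(ld_prune(panel, pd.Index(tab["variant"]), r2_prune,
                            inclusive=True))
    tab["pruned"] = [v not in kept_ids for v in tab["variant"]]
    return tab


def cluster_traits(
    projections: Sequence[Projection],
    components: Sequence[int] | None = None,
) -> tuple[np.ndarray, list[str], str]:
    """Ward.D2 hierarchical clustering of projected trait locations.

    Euclidean distances between delta vectors (optionally restricted to a
    component subset) are merged under Ward's minimum-variance criterion —
    scipy's ``ward`` linkage implements exactly the Ward.D2 update on
    Euclidean input. Ties break deterministically by input order. Returns
    the scipy linkage matrix, the trait labels, and a Newick string whose
    branch lengths are merge-height differences.
    """
    labels = [pr.trait_id for pr in projections]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate trait ids")
    if len(labels) < 2:
        raise ValueError("need at least two traits to cluster")
    x = np.vstack([pr.delta for pr in projections])
    if components is not None:
        x = x[:, list(components)]
    z = linkage(x, method="ward")
    tree = to_tree(z)

    def newick(node, parent_height: float) -> str:
        bl = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height - 0.0:.10g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    nwk = f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"
    return z, labels, nwk
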