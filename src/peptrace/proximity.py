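"""Distances from each bacterium to its closest eukaryotic homolog.

Three complementary metrics are computed per bacterial species and family:

* ``dist_E`` — evolutionary distance, the sum of branch lengths separating
  two leaves of the gene tree;
* ``dist_T`` — topological distance, the number of internal nodes on the
  path between two leaves (cherry partners count 1);
* ``dist_S`` — similarity distance, log10 of the best E-value of the
  bacterial sequence searched against the eukaryotic homologs.

Mixing a model-based, a topology-only and an alignment-score metric
hedges against tree-reconstruction artifacts: the top-k and pan-top-k
selections over these metrics flag candidate donor lineages, and rank-sum
comparisons ask whether homologs from AMP-resistant bacteria sit closer to
the eukaryotic copies than those of their non-resistant relatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from . import _hmm

METRICS = ("dist_E", "dist_T", "dist_S")
EVALUE_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# pairwise tree metrics
# ---------------------------------------------------------------------------

def evolutionary_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if leaf_a == leaf_b:
        tree.find(leaf_a)
        return 0.0
    return float(tree.find(leaf_a).distance(tree.find(leaf_b)))


def topological_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> int:
    """Number of internal nodes on the path between two leaves.

    Sister leaves of a cherry are separated by exactly one internal node
    (their parent).  Identical leaves give 0.
    """
    if leaf_a == leaf_b:
        tree.find(leaf_a)
        return 0
    na, nb = tree.find(leaf_a), tree.find(leaf_b)
    anc = [na] + list(na.ancestors())
    depth = {id(n): i for i, n in enumerate(anc)}
    steps = 0
    node = nb
    while id(node) not in depth:
        node = node.parent
        steps += 1
    edges = steps + depth[id(node)]
    return edges - 1


class TreeMetrics:
    """Cached all-pairs leaf distances for one gene tree."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        self.leaves = sorted(t.name for t in tree.tips())
        self._index = {n: i for i, n in enumerate(self.leaves)}
        dm = tree.tip_tip_distances()
        order = [list(dm.ids).index(n) for n in self.leaves]
        self.evolutionary = dm.data[np.ix_(order, order)]
        n = len(self.leaves)
        self.topological = np.zeros((n, n), dtype=int)
        for i, a in enumerate(self.leaves):
            for j in range(i + 1, n):
                d = topological_distance(tree, a, self.leaves[j])
                self.topological[i, j] = self.topological[j, i] = d

    def dist(self, metric: str, a: str, b: str) -> float:
        i, j = self._index[a], self._index[b]
        if metric == "dist_E":
            return float(self.evolutionary[i, j])
        if metric == "dist_T":
            return float(self.topological[i, j])
        raise ValueError(f"unknown tree metric {metric!r}")


# ---------------------------------------------------------------------------
# similarity distance
# ---------------------------------------------------------------------------

def similarity_distance(bacterial: tuple[str, str],
                        eukaryotes: Sequence[tuple[str, str]]
                        ) -> tuple[float, str] | None:
    """log10 best E-value of the bacterial sequence vs. the eukaryote set.

    Returns ``(log10 E, best eukaryote id)`` or ``None`` when no hit is
    reported.  E-values are floored at 1e-300 before taking the logarithm.
    """
    out = similarity_distances([bacterial], eukaryotes)
    return out.get(bacterial[0])


def similarity_distances(bacteria: Sequence[tuple[str, str]],
                         eukaryotes: Sequence[tuple[str, str]]
                         ) -> dict[str, tuple[float, str]]:
    """Batched :func:`similarity_distance` (one search pass, same results)."""
    if not eukaryotes:
        raise ValueError("eukaryote set is empty")
    out: dict[str, tuple[float, str]] = {}
    for qname, hits in _hmm.phmmer_search(list(bacteria), list(eukaryotes)):
        best = None
        for hit in hits:
            key = (float(hit.evalue), _hmm.as_str(hit.name))
            if best is None or key < best:
                best = key
        if best is not None:
            ev, eid = best
            out[qname] = (math.log10(max(ev, EVALUE_FLOOR)), eid)
    return out


# ---------------------------------------------------------------------------
# closest eukaryote and the proximity table
# ---------------------------------------------------------------------------

def closest_eukaryote(metrics: TreeMetrics,
                      gene_species: Mapping[str, str],
                      domain_of_species: Mapping[str, str],
                      species_id: str,
                      metric: str = "dist_E") -> tuple[float, str] | None:
    """Minimum distance from any homolog of a species to any eukaryotic leaf.

    A species with several homologs contributes its minimum; ties are broken
    by lexicographic eukaryote leaf id.  Returns ``None`` when the species
    has no homolog in the tree.
    """
    mine = [g for g in metrics.leaves if gene_species[g] == species_id]
    euks = [g for g in metrics.leaves
            if domain_of_species[gene_species[g]] == "Eukaryota"]
    if not euks:
        raise ValueError("tree has no eukaryotic leaves")
    if not mine:
        return None
    best = None
    for g in mine:
        for e in euks:
            key = (metrics.dist(metric, g, e), e, g)
            if best is None or key < best:
                best = key
    return best[0], best[1]


def proximity_table(tree: TreeNode,
                    gene_species: Mapping[str, str],
                    taxonomy: pd.DataFrame,
                    family: str,
                    sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """One row per bacterial species: distance to the closest eukaryote
    under each metric (``dist_S`` only when sequences are supplied).

    Missing values (species absent from the tree, or no similarity hit) are
    left as NaN and excluded per metric downstream, never imputed.
    """
    dom = taxonomy.set_index("species_id")["domain_of_life"].to_dict()
    metrics = TreeMetrics(tree)
    leaves = set(metrics.leaves)
    gs = {g: s for g, s in gene_species.items() if g in leaves}
    bact_species = sorted({s for s in gs.values() if dom[s] == "Bacteria"})
    euk_genes = [g for g, s in gs.items() if dom[s] == "Eukaryota"]

    sim: dict[str, tuple[float, str]] = {}
    if sequences is not None and euk_genes:
        bact_genes = [(g, sequences[g]) for g in sorted(gs)
                      if dom[gs[g]] == "Bacteria"]
        sim = similarity_distances(bact_genes, [(g, sequences[g])
                                                for g in sorted(euk_genes)])

    rows = []
    for sp in bact_species:
        row = {"species_id": sp, "family": family}
        for metric in ("dist_E", "dist_T"):
            res = closest_eukaryote(metrics, gs, dom, sp, metric) if euk_genes else None
            row[metric] = res[0] if res else np.nan
            row[f"closest_{metric}"] = res[1] if res else None
        best = None
        for g, s in gs.items():
            if s != sp or g not in sim:
                continue
            key = (*sim[g], g)
            if best is None or key < best:
                best = key
        row["dist_S"] = best[0] if best else np.nan
        row["closest_dist_S"] = best[1] if best else None
        rows.append(row)
    return pd.DataFrame(rows, columns=["species_id", "family", "dist_E", "dist_T",
                                       "dist_S", "closest_dist_E",
                                       "closest_dist_T", "closest_dist_S"])


# ---------------------------------------------------------------------------
# top-k selection
# ---------------------------------------------------------------------------

def top_k(records: pd.DataFrame, family: str, metric: str, k: int = 200
          ) -> list[str]:
    """The k bacterial species with the smallest distance under ``metric``.

    Records with a missing value for the metric are excluded; ties at the
    cut are resolved by species id, so the selection is deterministic.
    """
    sub = records[(records["family"] == family) & records[metric].notna()]
    ordered = sub.sort_values([metric, "species_id"], kind="mergesort")
    return ordered["species_id"].head(k).tolist()


def pan_top_k(records: pd.DataFrame, family: str, k: int = 200,
              metrics: Sequence[str] = METRICS) -> set[str]:
    """Union of the per-metric top-k species sets."""
    available = [m for m in metrics
                 if records[(records["family"] == family)][m].notna().any()]
    if not available:
        raise ValueError("no metric has values for this family")
    out: set[str] = set()
    for m in available:
        out.update(top_k(records, family, m, k))
    return out


# ---------------------------------------------------------------------------
# resistant vs. non-resistant comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    family: str
    clade: str
    metric: str
    computable: bool
    n_resistant: int = 0
    n_other: int = 0
    statistic: float = float("nan")
    p_value: float = float("nan")
    rank_biserial: float = float("nan")
    reason: str = ""


def compare_resistant(records: pd.DataFrame, taxonomy: pd.DataFrame,
                      family: str, clade: str, metric: str = "dist_E",
                      method: str = "auto") -> ComparisonReport:
    """One-sided rank-sum test: are resistant bacteria closer to eukaryotes?

    Tests, within one clade, whether the distances of AMP-resistant species
    are stochastically smaller than those of the other species of that
    clade (Mann-Whitney U, alternative "less").  Groups with fewer than two
    observations make the comparison not computable.  The rank-biserial
    effect size is ``1 - 2U/(n1*n2)`` (positive when resistant are closer).
    """
    tax = taxonomy.set_index("species_id")
    sub = records[(records["family"] == family) & records[metric].notna()].copy()
    sub = sub[sub["species_id"].map(lambda s: tax.loc[s, "clade"] == clade)]
    res_mask = sub["species_id"].map(lambda s: bool(tax.loc[s, "resistant"]))
    x = sub.loc[res_mask, metric].to_numpy(float)
    y = sub.loc[~res_mask, metric].to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        return ComparisonReport(family, clade, metric, computable=False,
                                n_resistant=len(x), n_other=len(y),
                                reason="a group has fewer than two observations")
    u, p = stats.mannwhitneyu(x, y, alternative="less", method=method)
    rb = 1.0 - 2.0 * float(u) / (len(x) * len(y))
    return ComparisonReport(family, clade, metric, computable=True,
                            n_resistant=len(x), n_other=len(y),
                            statistic=float(u), p_value=float(p),
                            rank_biserial=rb)
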