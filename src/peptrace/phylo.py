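"""Gene-tree construction and the tree operations the analysis relies on.

Trees are :class:`skbio.TreeNode` objects read/written as newick, with any
per-leaf annotations (species, domain of life, clade, resistance, family)
carried in a sidecar table rather than in the newick string.  Internal node
names are treated as opaque support labels and carried through rooting and
collapsing unchanged.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import _hmm

GAP_CHARS = set(".-")


# ---------------------------------------------------------------------------
# motif-concatenated alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A concatenated multiple alignment with per-motif column spans."""

    names: list[str]
    rows: list[str]
    motif_spans: list[tuple[str, int, int]] = field(default_factory=list)
    # (motif_id, start_col, end_col), 0-based half-open

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.names, self.rows))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, r in zip(self.names, self.rows):
                fh.write(f">{n}\n{r}\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO
        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq))
        return cls(names, rows)


def align_family_motifs(sequences: Mapping[str, str],
                        domain_hits: Mapping[str, Sequence],
                        composition: Sequence[str],
                        motif_models: Mapping[str, str],
                        motifs: Sequence[str] | None = None) -> Alignment:
    """Extract, align and concatenate the family's motif instances.

    For each slot of the composition (the stromal-processing-peptidase
    architecture lists its M16C-like motif twice, giving two slots) the
    corresponding motif instance is cut out of every homolog, the instances
    are aligned against the motif's profile, and the per-slot alignments
    are concatenated in composition order.  ``motifs`` restricts the slots
    to a subset (e.g. only the two motifs shared by all M16-family
    peptidases, for a combined tree).  Homologs missing a required slot are
    excluded with a warning.
    """
    slots: list[tuple[str, int]] = []  # (motif_id, occurrence index)
    seen: Counter = Counter()
    for m in composition:
        if motifs is None or m in motifs:
            slots.append((m, seen[m]))
        seen[m] += 1
    if not slots:
        raise ValueError("no motif slots selected")

    usable: list[str] = []
    pieces: dict[str, list[str]] = {}
    for gene in sorted(sequences):
        hits = sorted((h for h in domain_hits.get(gene, [])),
                      key=lambda h: h.start)
        per_motif: dict[str, list] = {}
        for h in hits:
            per_motif.setdefault(h.motif_id, []).append(h)
        parts, ok = [], True
        for motif_id, occ in slots:
            inst = per_motif.get(motif_id, [])
            if occ >= len(inst):
                ok = False
                break
            h = inst[occ]
            parts.append(sequences[gene][h.start - 1:h.end])
        if not ok:
            warnings.warn(f"{gene}: missing required motif; excluded from alignment")
            continue
        usable.append(gene)
        pieces[gene] = parts
    if not usable:
        return Alignment([], [])

    columns: list[dict[str, str]] = []
    spans: list[tuple[str, int, int]] = []
    offset = 0
    for j, (motif_id, _occ) in enumerate(slots):
        hmm = _hmm.build_hmm_from_sequence(motif_id, motif_models[motif_id])
        msa = _hmm.align_to_hmm(hmm, [(g, pieces[g][j]) for g in usable])
        aligned = {n: s.replace(".", "-").upper()
                   for n, s in zip(msa.names, msa.alignment)}
        width = len(next(iter(aligned.values())))
        spans.append((motif_id, offset, offset + width))
        offset += width
        columns.append(aligned)
    rows = ["".join(block[g] for block in columns) for g in usable]
    return Alignment(usable, rows, spans)


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def alignment_distances(alignment: Alignment, max_distance: float = 5.0
                        ) -> DistanceMatrix:
    """Poisson-corrected pairwise distances over shared non-gap columns."""
    order = sorted(range(len(alignment.names)), key=lambda i: alignment.names[i])
    names = [alignment.names[i] for i in order]
    mats = np.array([list(alignment.rows[i]) for i in order])
    is_res = ~np.isin(mats, list(GAP_CHARS))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = is_res[i] & is_res[j]
            ns = int(shared.sum())
            if ns == 0:
                dist = max_distance
            else:
                p = float((mats[i, shared] != mats[j, shared]).mean())
                dist = max_distance if p >= 1.0 else min(-np.log(1.0 - p), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=names)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with negative branch lengths clamped to zero."""
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def infer_tree(alignment: Alignment, method: str = "nj") -> TreeNode:
    """Build a gene tree from a concatenated motif alignment.

    The default is deterministic neighbor joining on Poisson-corrected
    distances; rows are sorted by name first so the result is independent
    of input order.  ``method="nj"`` is the only built-in; an external
    approximate-maximum-likelihood tool can be slotted in by passing a
    callable taking the alignment and returning a ``TreeNode``.
    """
    if len(alignment.names) < 3:
        raise ValueError("tree inference needs at least 3 sequences")
    if callable(method):
        return method(alignment)
    if method != "nj":
        raise ValueError(f"unknown method {method!r}")
    return nj_tree(alignment_distances(alignment))


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: TreeNode):
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    nodes: dict[int, TreeNode] = {}
    for n in tree.traverse(include_self=True):
        nodes[id(n)] = n
        adj.setdefault(id(n), [])
    for n in tree.traverse(include_self=False):
        L = float(n.length or 0.0)
        adj[id(n.parent)].append((n, L))
        adj[id(n)].append((n.parent, L))
    return adj, nodes


def _tip_path(adj, start: TreeNode, goal: TreeNode) -> list[tuple[TreeNode, float]]:
    """Unique path start..goal as [(node, length_to_previous)]."""
    prev: dict[int, tuple[TreeNode, float]] = {id(start): (None, 0.0)}
    stack = [start]
    while stack:
        node = stack.pop()
        if node is goal:
            break
        for nb, L in adj[id(node)]:
            if id(nb) not in prev:
                prev[id(nb)] = (node, L)
                stack.append(nb)
    path = []
    node, L = goal, 0.0
    while node is not None:
        path.append((node, L))
        node, L = prev[id(node)]
    path.reverse()
    # path[i][1] is the length of the edge (path[i], path[i+1]); re-attach
    # each edge length to its far endpoint so out[i] pairs a node with the
    # length of the edge leading to it from out[i-1]
    out = [(path[0][0], 0.0)]
    for i in range(1, len(path)):
        out.append((path[i][0], path[i - 1][1]))
    return out


def _orient(adj, node: TreeNode, parent: TreeNode | None, length: float | None
            ) -> TreeNode:
    children = [_orient(adj, nb, node, L) for nb, L in adj[id(node)]
                if nb is not parent]
    new = TreeNode(name=node.name, length=length, children=children)
    return new


def _suppress_unary(tree: TreeNode) -> TreeNode:
    for node in list(tree.postorder(include_self=False)):
        if len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            node.children = []
            parent.children[idx] = child
            child.parent = parent
    return tree


def midpoint_root(tree: TreeNode, tolerance: float = 1e-12) -> TreeNode:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    The two diameter endpoints end up equidistant from the returned root
    (within floating-point error).  Trees whose branch lengths are all zero
    have no defined midpoint; they are returned rooted as given, with a
    warning.  The operation is idempotent: re-rooting a midpoint-rooted
    tree reproduces the same root position.
    """
    tips = sorted(tree.tips(), key=lambda t: t.name or "")
    if len(tips) < 2:
        return tree.copy()
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    data = dm.data
    best, best_pair = -1.0, None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if data[i, j] > best + tolerance:
                best, best_pair = data[i, j], (ids[i], ids[j])
    if best <= tolerance:
        warnings.warn("all branch lengths are zero; midpoint undefined, "
                      "returning tree rooted as given")
        return tree.copy()

    adj, _nodes = _adjacency(tree)
    a = tree.find(best_pair[0])
    b = tree.find(best_pair[1])
    path = _tip_path(adj, a, b)
    half = best / 2.0
    cum = 0.0
    for k in range(1, len(path)):
        node_u, _ = path[k - 1]
        node_v, L = path[k]
        if cum + L >= half - tolerance:
            x = half - cum  # distance from node_u along edge (u, v)
            if x <= tolerance and not node_u.is_tip():
                root = _orient(adj, node_u, None, None)
            elif L - x <= tolerance and not node_v.is_tip():
                root = _orient(adj, node_v, None, None)
            else:
                left = _orient(adj, node_u, node_v, x)
                right = _orient(adj, node_v, node_u, L - x)
                root = TreeNode(children=[left, right])
            return _suppress_unary(root)
        cum += L
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


# ---------------------------------------------------------------------------
# clade queries
# ---------------------------------------------------------------------------

def is_monophyletic(tree: TreeNode, leaves: Iterable[str]
                    ) -> tuple[bool, TreeNode]:
    """Whether ``leaves`` form a complete clade of the rooted tree.

    Returns the verdict and the smallest clade containing the leaf set.
    """
    wanted = set(leaves)
    if not wanted:
        raise ValueError("empty leaf subset")
    tip_names = {t.name for t in tree.tips()}
    missing = wanted - tip_names
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    if wanted == tip_names:
        return True, tree
    if len(wanted) == 1:
        return True, tree.find(next(iter(wanted)))
    lca = tree.lca(sorted(wanted))
    clade = {t.name for t in lca.tips()}
    return clade == wanted, lca


def collapse_by_group(tree: TreeNode, group_of: Mapping[str, str]) -> TreeNode:
    """Collapse every maximal single-group clade into one pseudo-leaf.

    Pseudo-leaves are named after their group and carry a ``count``
    attribute with the number of original leaves they replace; leaf counts
    are conserved.  Raises if any leaf lacks a group label.
    """
    for tip in tree.tips():
        if tip.name not in group_of:
            raise KeyError(f"leaf {tip.name!r} has no group label")

    def rec(node: TreeNode) -> tuple[TreeNode, set[str], int]:
        if node.is_tip():
            new = TreeNode(name=node.name, length=node.length)
            new.count = 1
            new.group = group_of[node.name]
            return new, {group_of[node.name]}, 1
        results = [rec(c) for c in node.children]
        groups = set().union(*(g for _, g, _ in results))
        total = sum(n for _, _, n in results)
        if len(groups) == 1:
            pseudo = TreeNode(name=next(iter(groups)), length=node.length)
            pseudo.count = total
            pseudo.group = next(iter(groups))
            return pseudo, groups, total
        new = TreeNode(name=node.name, length=node.length,
                       children=[r for r, _, _ in results])
        new.count = total
        return new, groups, total

    collapsed, _, _ = rec(tree)
    return collapsed


def count_misclassified(tree: TreeNode, family_of: Mapping[str, str]
                        ) -> pd.DataFrame:
    """Count, per family, members falling outside the family's core clade.

    The core clade of a family is the clade (any node, including single
    leaves) maximising the F1 score between its leaf set and the family's
    leaf set; ties prefer the smaller clade.  ``misclassified`` counts
    family members outside the core clade, ``foreign`` counts other leaves
    inside it.
    """
    for tip in tree.tips():
        if tip.name not in family_of:
            raise KeyError(f"leaf {tip.name!r} has no family label")
    totals = Counter(family_of[t.name] for t in tree.tips())

    best: dict[str, tuple[float, int, int]] = {f: (-1.0, 0, 0) for f in totals}
    counts: dict[int, Counter] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            c = Counter([family_of[node.name]])
        else:
            c = Counter()
            for child in node.children:
                c.update(counts[id(child)])
        counts[id(node)] = c
        size = sum(c.values())
        for fam, tp in c.items():
            f1 = 2.0 * tp / (size + totals[fam])
            cur = best[fam]
            if f1 > cur[0] + 1e-12 or (abs(f1 - cur[0]) <= 1e-12 and size < cur[2]):
                best[fam] = (f1, tp, size)

    rows = []
    for fam in sorted(totals):
        f1, tp, size = best[fam]
        rows.append({"family": fam, "n_members": totals[fam],
                     "core_clade_size": size, "misclassified": totals[fam] - tp,
                     "foreign": size - tp, "f1": f1})
    return pd.DataFrame(rows, columns=["family", "n_members", "core_clade_size",
                                       "misclassified", "foreign", "f1"])


def clade_tree_from_species(species_tree: TreeNode,
                            clade_of_species: Mapping[str, str]) -> TreeNode:
    """Collapse a species tree to the clade level (clades are monophyletic)."""
    return collapse_by_group(species_tree, clade_of_species)
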