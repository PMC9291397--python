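"""Synthetic gene-family evolution fixtures with known ground truth.

This module generates the inputs the rest of the pipeline consumes: a
time-calibrated species tree whose leaves carry domain-of-life / clade /
genus / AMP-resistance labels, gene families evolving along that tree by
duplication, loss, intra-bacterial horizontal transfer (HGT) and scripted
bacteria-to-eukaryote endosymbiotic transfers (EGT), and protein sequences
composed of conserved domain blocks separated by fast-evolving linkers.

Every stochastic choice is driven by a single root seed so that identical
specifications produce byte-identical fixtures, and every simulated event
is recorded in an :class:`EventLog` that downstream tests treat as ground
truth.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Depth (in time units) of the whole species tree; leaves sit at this time.
TREE_DEPTH = 1.0
#: Time of the bacterial / (archaeal+eukaryotic) root split.
T_PRIMARY_SPLIT = 0.15
#: Time of the archaea / eukaryote split.
T_ARCH_EUK_SPLIT = 0.35
#: All inter-clade backbone joins within bacteria finish by this time, so
#: every clade has a pure stem branch alive from here until its MRCA.
T_BACKBONE_END = 0.25
#: Time at which every clade's most recent common ancestor is placed.
T_CLADE_ROOT = 0.5

GENUS_SIZE = 3

DOMAINS = ("Bacteria", "Archaea", "Eukaryota")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladePlan:
    """One monophyletic clade of the simulated species tree."""

    name: str
    domain_of_life: str
    n_species: int
    resistant_fraction: float = 0.0


@dataclass
class SpeciesTreeSpec:
    """Layout of the simulated species tree.

    ``clade_plan`` fully determines the leaf set; the per-domain counts are
    derived from it.  ``resistant_fraction`` is realised at the genus level
    (whole genera are flagged resistant) to mirror how antimicrobial-peptide
    resistance annotations are assigned in the literature.
    """

    clade_plan: Sequence[CladePlan]
    seed: int = 0

    @property
    def n_bacteria(self) -> int:
        return sum(c.n_species for c in self.clade_plan if c.domain_of_life == "Bacteria")

    @property
    def n_eukaryotes(self) -> int:
        return sum(c.n_species for c in self.clade_plan if c.domain_of_life == "Eukaryota")

    @property
    def n_archaea(self) -> int:
        return sum(c.n_species for c in self.clade_plan if c.domain_of_life == "Archaea")

    def validate(self) -> None:
        if not self.clade_plan:
            raise ValueError("clade_plan is empty")
        names = [c.name for c in self.clade_plan]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clade names")
        for c in self.clade_plan:
            if c.domain_of_life not in DOMAINS:
                raise ValueError(f"unknown domain of life: {c.domain_of_life!r}")
            if c.n_species < 1:
                raise ValueError(f"clade {c.name!r} has {c.n_species} species")
            if not 0.0 <= c.resistant_fraction <= 1.0:
                raise ValueError("resistant_fraction outside [0, 1]")
            if c.resistant_fraction > 0 and c.domain_of_life != "Bacteria":
                raise ValueError("resistant_fraction only applies to bacterial clades")


@dataclass(frozen=True)
class EgtEvent:
    """A scripted bacteria-to-eukaryote transfer.

    ``recipient`` is either an internal-branch name of the species tree or
    the form ``"stem:<group>"``, naming the branch immediately above the
    most recent common ancestor of a clade, or of all leaves of one domain
    of life.  ``time`` is absolute (0 = species-tree root).
    """

    donor_clade: str
    recipient: str
    time: float


@dataclass
class FamilySpec:
    """Evolutionary parameters of one simulated peptidase family.

    Rates are events per gene lineage per unit branch length.  The ordered
    ``domain_blocks`` define the domain architecture of every member;
    substitutions accumulate more slowly inside blocks
    (``core_rate_multiplier``) than in linkers (``linker_rate_multiplier``).
    ``block_loss_rate`` governs whole-block deletions (per block per unit
    branch length), producing composition-filter negatives downstream.
    """

    family_name: str
    domain_blocks: Sequence[str]
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    hgt_rate: float = 0.0
    egt_events: Sequence[EgtEvent] = field(default_factory=tuple)
    core_rate_multiplier: float = 0.3
    linker_rate_multiplier: float = 1.0
    site_rate: float = 0.3
    block_loss_rate: float = 0.05
    origin: str = "bacteria"  # or "root"

    def validate(self) -> None:
        if not self.domain_blocks:
            raise ValueError("domain_blocks must be nonempty")
        for r in (self.dup_rate, self.loss_rate, self.hgt_rate,
                  self.site_rate, self.block_loss_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.core_rate_multiplier <= 1:
            raise ValueError("core_rate_multiplier must be in [0, 1]")
        if self.linker_rate_multiplier < 1:
            raise ValueError("linker_rate_multiplier must be >= 1")
        if self.core_rate_multiplier > self.linker_rate_multiplier:
            raise ValueError("core multiplier must not exceed linker multiplier")
        if self.origin not in ("bacteria", "root"):
            raise ValueError("origin must be 'bacteria' or 'root'")


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

#: lengths of the built-in motif models; the M16-like block is long enough
#: to embed the catalytic zinc-binding pattern HxxEH...(76)...E.
DEFAULT_MOTIF_LENGTHS = {
    "M16": 90,
    "M16C": 80,
    "M16C_assoc": 70,
    "M3": 120,
    "ZF1": 40,
    "TM9": 36,
}

#: 1-based offsets of the catalytic residues inside the M16-like block:
#: H at 3, E at 6, H at 7, then 76 spacer positions, then E at 84.
CATALYTIC_LAYOUT = {3: "H", 6: "E", 7: "H", 84: "E"}
CATALYTIC_MOTIF_ID = "M16"

DEFAULT_COMPOSITIONS: dict[str, tuple[str, ...]] = {
    "MPP": ("M16", "M16C"),
    "PreP": ("M16", "M16C", "M16C_assoc"),
    "SPP": ("M16", "M16C", "M16C"),
    "OOP": ("M3",),
}


class MotifLibrary:
    """Consensus sequences of the conserved domain blocks.

    Each motif id maps to a fixed consensus string from which family root
    sequences are assembled and from which single-sequence profile HMMs can
    be built for domain annotation.
    """

    def __init__(self, consensus: Mapping[str, str]):
        self.consensus = dict(consensus)

    @classmethod
    def default(cls, seed: int = 2027) -> "MotifLibrary":
        rng = np.random.default_rng(seed)
        cons = {}
        for motif_id in sorted(DEFAULT_MOTIF_LENGTHS):
            length = DEFAULT_MOTIF_LENGTHS[motif_id]
            chars = list(rng.choice(list(AMINO_ACIDS), size=length))
            if motif_id == CATALYTIC_MOTIF_ID:
                for pos, res in CATALYTIC_LAYOUT.items():
                    chars[pos - 1] = res
            cons[motif_id] = "".join(chars)
        return cls(cons)

    def __getitem__(self, motif_id: str) -> str:
        return self.consensus[motif_id]

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self.consensus

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifLibrary) and self.consensus == other.consensus

    def to_frame(self) -> pd.DataFrame:
        rows = [{"motif_id": m, "consensus": s} for m, s in sorted(self.consensus.items())]
        return pd.DataFrame(rows, columns=["motif_id", "consensus"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifLibrary":
        return cls(dict(zip(df["motif_id"], df["consensus"])))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _coalesce(subtrees: list[TreeNode], t_root: float, rng: np.random.Generator,
              t_max: float | None = None) -> TreeNode:
    """Join subtrees into one binary tree whose root sits at ``t_root``.

    Join times are drawn uniformly between ``t_root`` and ``t_max`` (capped
    at the earliest subtree root) and applied latest-first, which
    guarantees parent times strictly precede child times.
    """
    if len(subtrees) == 1:
        return subtrees[0]
    t_min = min(st.time for st in subtrees)
    if t_max is not None:
        t_min = min(t_min, t_max)
    k = len(subtrees) - 1
    times = sorted(rng.uniform(t_root, t_min, size=k - 1), reverse=True) if k > 1 else []
    times.append(t_root)
    roots = list(subtrees)
    for t in times:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        node = TreeNode(children=[roots[i], roots[j]])
        node.time = t
        roots = [r for idx, r in enumerate(roots) if idx not in (i, j)]
        roots.append(node)
    return roots[0]


def _clade_subtree(species: list[str], t_root: float, rng: np.random.Generator) -> TreeNode:
    leaves = []
    for sp in species:
        leaf = TreeNode(name=sp)
        leaf.time = TREE_DEPTH
        leaves.append(leaf)
    if len(leaves) == 1:
        return leaves[0]
    return _coalesce(leaves, t_root, rng)


def simulate_species_tree(spec: SpeciesTreeSpec) -> TreeNode:
    """Simulate a labeled, ultrametric, binary species tree.

    Clades are grafted as monophyletic subtrees under a fixed backbone
    (bacteria vs. archaea+eukaryotes); all leaves sit at time 1.0 so that
    transfer events can reference a common absolute clock.  Leaves carry a
    ``taxon`` dict with species id, domain of life, clade, genus and the
    genus-level resistance flag.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    domain_subtrees: dict[str, list[TreeNode]] = {d: [] for d in DOMAINS}
    taxa: dict[str, dict] = {}
    for clade in spec.clade_plan:
        species = [f"{clade.name}_{i + 1:02d}" for i in range(clade.n_species)]
        genera = {}
        for i, sp in enumerate(species):
            genera[sp] = f"{clade.name}_g{i // GENUS_SIZE + 1}"
        resistant_genera = _pick_resistant_genera(species, genera, clade.resistant_fraction, rng)
        for sp in species:
            taxa[sp] = {
                "species_id": sp,
                "domain_of_life": clade.domain_of_life,
                "clade": clade.name,
                "genus": genera[sp],
                "resistant": int(genera[sp] in resistant_genera),
            }
        domain_subtrees[clade.domain_of_life].append(_clade_subtree(species, T_CLADE_ROOT, rng))

    bact = _coalesce(domain_subtrees["Bacteria"], T_PRIMARY_SPLIT, rng,
                     t_max=T_BACKBONE_END) if domain_subtrees["Bacteria"] else None
    arch = _coalesce(domain_subtrees["Archaea"], T_ARCH_EUK_SPLIT, rng,
                     t_max=T_CLADE_ROOT) if domain_subtrees["Archaea"] else None
    euk = _coalesce(domain_subtrees["Eukaryota"], T_ARCH_EUK_SPLIT, rng,
                    t_max=T_CLADE_ROOT) if domain_subtrees["Eukaryota"] else None

    if arch is not None and euk is not None:
        ae = TreeNode(children=[arch, euk])
        ae.time = T_PRIMARY_SPLIT
    else:
        ae = arch if arch is not None else euk

    tops = [t for t in (bact, ae) if t is not None]
    if len(tops) == 2:
        root = TreeNode(children=tops)
        root.time = 0.0
    else:
        root = tops[0]

    _finalize_tree(root, taxa)
    return root


def _pick_resistant_genera(species, genera, fraction, rng) -> set[str]:
    if fraction <= 0:
        return set()
    target = round(fraction * len(species))
    genus_names = sorted(set(genera.values()))
    order = list(rng.permutation(genus_names))
    chosen: set[str] = set()
    count = 0
    for g in order:
        if count >= target:
            break
        chosen.add(g)
        count += sum(1 for sp in species if genera[sp] == g)
    return chosen


def _finalize_tree(root: TreeNode, taxa: dict[str, dict]) -> None:
    """Set branch lengths from node times, name internal nodes, attach taxa."""
    root.length = None
    counter = 0
    for node in root.preorder():
        if node.parent is not None:
            node.length = node.time - node.parent.time
        if node.is_tip():
            node.taxon = taxa[node.name]
        elif node is not root:
            counter += 1
            node.name = f"n{counter:03d}"
        else:
            node.name = "root"


def taxonomy_table(species_tree: TreeNode) -> pd.DataFrame:
    """Extract the per-species taxonomy annotations as a DataFrame."""
    rows = [dict(tip.taxon) for tip in species_tree.tips()]
    df = pd.DataFrame(rows, columns=["species_id", "domain_of_life", "clade", "genus", "resistant"])
    return df.sort_values("species_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene family simulation
# ---------------------------------------------------------------------------

class _GeneNode:
    __slots__ = ("uid", "t0", "t1", "children", "dead", "gene_id", "species")

    def __init__(self, uid: str, t0: float):
        self.uid = uid
        self.t0 = t0
        self.t1: float | None = None
        self.children: list["_GeneNode"] = []
        self.dead = False
        self.gene_id: str | None = None
        self.species: str | None = None


@dataclass
class EventLog:
    """Ground-truth record of one simulated family.

    ``events`` is chronological; each entry names the species-tree branch
    (by child-node name), the gene-tree node involved and, for transfers,
    donor/recipient information.  ``genes`` maps every extant gene id to its
    species.
    """

    family: str
    events: list[dict] = field(default_factory=list)
    genes: dict[str, str] = field(default_factory=dict)

    def extant_count(self) -> int:
        return len(self.genes)

    def species_counts(self) -> pd.Series:
        return pd.Series(self.genes, name="species").value_counts().sort_index()

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "events": self.events,
                           "genes": self.genes}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        d = json.loads(text)
        return cls(family=d["family"], events=d["events"], genes=d["genes"])

    def validate(self) -> None:
        for ev in self.events:
            if ev["kind"] not in ("duplication", "loss", "hgt", "egt"):
                raise ValueError(f"unknown event kind {ev['kind']!r}")


def _resolve_recipient(species_tree: TreeNode, recipient: str) -> TreeNode:
    if recipient.startswith("stem:"):
        group = recipient.split(":", 1)[1]
        tips = [t for t in species_tree.tips()
                if t.taxon["clade"] == group or t.taxon["domain_of_life"] == group]
        if not tips:
            raise ValueError(f"no species in group {group!r}")
        if len(tips) == 1:
            return tips[0]
        node = species_tree.lca([t.name for t in tips])
        if node.is_root():
            raise ValueError(f"group {group!r} spans the root; no stem branch exists")
        return node
    try:
        return species_tree.find(recipient)
    except Exception as exc:  # skbio MissingNodeError
        raise ValueError(f"unknown recipient branch {recipient!r}") from exc


def simulate_family(species_tree: TreeNode, fspec: FamilySpec, seed: int
                    ) -> tuple[TreeNode | None, EventLog]:
    """Evolve one gene family along the species tree.

    A Gillespie sweep runs a birth-death-transfer process forward in time:
    each extant gene lineage duplicates, dies or (on bacterial branches)
    transfers to a contemporaneous bacterial branch at the specified rates;
    scripted EGT events copy a random donor-clade lineage onto the recipient
    branch at the scripted time.  Returns the pruned extant gene tree (or
    ``None`` if the family went extinct) and the complete event log.

    The family originates as a single lineage on the branch above the
    bacterial (``origin="bacteria"``, default) or root (``origin="root"``)
    ancestor, so eukaryotes only acquire members through scripted EGT when
    the origin is bacterial.
    """
    fspec.validate()
    rng = np.random.default_rng(seed)
    log = EventLog(family=fspec.family_name)

    clades = {t.taxon["clade"] for t in species_tree.tips()}
    for ev in fspec.egt_events:
        if ev.donor_clade not in clades:
            raise ValueError(f"donor clade {ev.donor_clade!r} absent from species tree")

    branches: list[TreeNode] = [n for n in species_tree.preorder() if n.parent is not None]
    bacterial = {id(b): all(t.taxon["domain_of_life"] == "Bacteria" for t in b.tips(include_self=True))
                 for b in branches}
    t_start = {id(b): b.parent.time for b in branches}
    t_end = {id(b): b.time for b in branches}

    egt_resolved = []
    for ev in fspec.egt_events:
        rec = _resolve_recipient(species_tree, ev.recipient)
        if rec.parent is None:
            raise ValueError("recipient cannot be the root")
        if not (t_start[id(rec)] <= ev.time < t_end[id(rec)]):
            raise ValueError(
                f"EGT time {ev.time} outside recipient branch interval "
                f"({t_start[id(rec)]}, {t_end[id(rec)]})")
        egt_resolved.append((ev, rec))

    # origin lineage
    if fspec.origin == "bacteria":
        bact_tips = [t.name for t in species_tree.tips()
                     if t.taxon["domain_of_life"] == "Bacteria"]
        if not bact_tips:
            raise ValueError("bacterial origin requested but tree has no bacteria")
        origin = species_tree.lca(bact_tips) if len(bact_tips) > 1 \
            else species_tree.find(bact_tips[0])
        if origin.parent is None:
            origin = origin.children[0]  # degenerate: all-bacteria tree
    else:
        origin = species_tree.children[0]

    uid_counter = [0]

    def new_node(t0: float) -> _GeneNode:
        uid_counter[0] += 1
        return _GeneNode(f"{fspec.family_name}.n{uid_counter[0]:04d}", t0)

    root_gene = new_node(t_start[id(origin)])
    lineages: list[tuple[_GeneNode, TreeNode]] = [(root_gene, origin)]
    if fspec.origin == "root" and len(species_tree.children) == 2:
        # one ancestral gene copied into both root children
        root_gene.t1 = 0.0
        for child in species_tree.children:
            g = new_node(0.0)
            root_gene.children.append(g)
        lineages = list(zip(root_gene.children, species_tree.children))

    boundary_times = sorted({n.time for n in species_tree.preorder() if n.parent is not None}
                            | {ev.time for ev, _ in egt_resolved})
    t = min(g.t0 for g, _ in lineages)

    def alive_bacterial_branches(now: float) -> list[TreeNode]:
        return [b for b in branches
                if bacterial[id(b)] and t_start[id(b)] <= now < t_end[id(b)]]

    for t_next in boundary_times:
        if t_next <= t:
            continue
        # --- Gillespie within (t, t_next)
        while lineages:
            rates = []
            for g, b in lineages:
                r = fspec.dup_rate + fspec.loss_rate
                if bacterial[id(b)]:
                    r += fspec.hgt_rate
                rates.append(r)
            total = float(sum(rates))
            if total == 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_next:
                break
            t += dt
            idx = rng.choice(len(lineages), p=np.asarray(rates) / total)
            g, b = lineages[idx]
            r_hgt = fspec.hgt_rate if bacterial[id(b)] else 0.0
            u = rng.uniform(0, rates[idx])
            if u < fspec.dup_rate:
                g.t1 = t
                c1, c2 = new_node(t), new_node(t)
                g.children = [c1, c2]
                lineages[idx] = (c1, b)
                lineages.append((c2, b))
                log.events.append({"kind": "duplication", "time": t, "branch": b.name,
                                   "gene": g.uid, "children": [c1.uid, c2.uid]})
            elif u < fspec.dup_rate + fspec.loss_rate:
                g.t1 = t
                g.dead = True
                del lineages[idx]
                log.events.append({"kind": "loss", "time": t, "branch": b.name,
                                   "gene": g.uid})
            else:
                targets = [x for x in alive_bacterial_branches(t) if x is not b]
                if not targets:
                    continue
                rec = targets[rng.choice(len(targets))]
                g.t1 = t
                stay, moved = new_node(t), new_node(t)
                g.children = [stay, moved]
                lineages[idx] = (stay, b)
                lineages.append((moved, rec))
                log.events.append({"kind": "hgt", "time": t, "donor_branch": b.name,
                                   "recipient_branch": rec.name, "gene": g.uid,
                                   "children": [stay.uid, moved.uid]})
        t = t_next
        # --- scripted EGTs at this instant
        for ev, rec in egt_resolved:
            if ev.time != t_next:
                continue
            donors = [(i, g, b) for i, (g, b) in enumerate(lineages)
                      if any(tip.taxon["clade"] == ev.donor_clade
                             for tip in b.tips(include_self=True))
                      and all(tip.taxon["clade"] == ev.donor_clade
                              for tip in b.tips(include_self=True))]
            entry = {"kind": "egt", "time": t, "donor_clade": ev.donor_clade,
                     "recipient_branch": rec.name}
            if not donors:
                entry.update({"gene": None, "children": [], "no_donor": True})
                log.events.append(entry)
                continue
            i, g, b = donors[rng.choice(len(donors))]
            g.t1 = t
            stay, moved = new_node(t), new_node(t)
            g.children = [stay, moved]
            lineages[i] = (stay, b)
            lineages.append((moved, rec))
            entry.update({"gene": g.uid, "donor_branch": b.name,
                          "children": [stay.uid, moved.uid]})
            log.events.append(entry)
        # --- speciations / leaf terminations at this instant
        new_lineages = []
        for g, b in lineages:
            if t_end[id(b)] != t_next:
                new_lineages.append((g, b))
                continue
            g.t1 = t_next
            if b.is_tip():
                g.gene_id = ""  # extant; id assigned below
                g.species = b.name
            else:
                for child in b.children:
                    c = new_node(t_next)
                    g.children.append(c)
                    new_lineages.append((c, child))
        lineages = new_lineages
        if not lineages:
            break

    # assign stable gene ids to extant leaves, in simulation order
    extant = _collect_extant(root_gene)
    for i, g in enumerate(extant, start=1):
        g.gene_id = f"{fspec.family_name}_{i:04d}"
        log.genes[g.gene_id] = g.species

    for entry in log.events:
        if entry["kind"] == "egt" and entry.get("gene") is not None:
            moved_uid = entry["children"][1]
            entry["survived"] = _uid_has_extant(root_gene, moved_uid)

    tree = _prune_gene_tree(root_gene)
    return tree, log


def _collect_extant(node: _GeneNode) -> list[_GeneNode]:
    out = []
    stack = [node]
    while stack:
        g = stack.pop()
        if g.species is not None:
            out.append(g)
        stack.extend(reversed(g.children))
    return sorted(out, key=lambda g: g.uid)


def _uid_has_extant(root: _GeneNode, uid: str) -> bool:
    def find(g):
        if g.uid == uid:
            return g
        for c in g.children:
            r = find(c)
            if r is not None:
                return r
        return None

    node = find(root)
    return node is not None and len(_collect_extant(node)) > 0


def _prune_gene_tree(root_gene: _GeneNode) -> TreeNode | None:
    def convert(g: _GeneNode) -> TreeNode | None:
        span = (g.t1 if g.t1 is not None else g.t0) - g.t0
        if g.species is not None:
            node = TreeNode(name=g.gene_id, length=span)
            node.species = g.species
            return node
        kept = [c for c in (convert(ch) for ch in g.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += span
            return kept[0]
        return TreeNode(children=kept, length=span)

    tree = convert(root_gene)
    if tree is not None:
        tree.length = None
        counter = 0
        for node in tree.preorder():
            if not node.is_tip() and node.name is None:
                counter += 1
                node.name = f"i{counter:03d}"
    return tree


def gene_species_map(gene_tree: TreeNode) -> dict[str, str]:
    return {tip.name: tip.species for tip in gene_tree.tips()}


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

#: per-site probability by which a family's root copy of a block differs
#: from the library consensus; gives the families of a shared block (e.g.
#: the three M16-type peptidases) distinguishable sequence signatures.
FAMILY_BLOCK_DIVERGENCE = 0.25


def family_root_block(family: str, motif_id: str, lib: MotifLibrary,
                      divergence: float = FAMILY_BLOCK_DIVERGENCE) -> list[str]:
    """Deterministic family-specific variant of a block consensus.

    Seeded from a CRC of (family, motif) so it is stable across runs and
    independent of the simulation seed.  Catalytic positions of the
    M16-like block are never touched.
    """
    import zlib

    rng = np.random.default_rng(zlib.crc32(f"{family}|{motif_id}".encode()))
    chars = list(lib[motif_id])
    protect = set(CATALYTIC_LAYOUT) if motif_id == CATALYTIC_MOTIF_ID else set()
    aa = list(AMINO_ACIDS)
    for i in range(len(chars)):
        if (i + 1) in protect:
            continue
        if rng.random() < divergence:
            chars[i] = str(rng.choice(aa))
    return chars


def evolve_sequences(gene_tree: TreeNode, fspec: FamilySpec,
                     root_linker_length: int, seed: int,
                     motif_library: MotifLibrary | None = None,
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Emit one protein sequence per extant gene of ``gene_tree``.

    The root sequence concatenates the family's domain blocks (motif-library
    consensus sequences) flanked and separated by random linkers of length
    ``root_linker_length``.  Along each branch every site substitutes with
    probability ``1 - exp(-site_rate * multiplier * length)`` (uniform
    replacement over the 20 amino acids) and linker lengths are re-drawn
    from a Poisson around ``root_linker_length`` (creating alignment gaps).
    Whole-block deletions are applied per terminal lineage: each block of a
    gene is dropped with probability
    ``1 - exp(-block_loss_rate * root_to_tip_path)``, independently across
    genes, producing composition-filter negatives without wiping entire
    clades.

    Returns ``(sequences, blocks)`` where ``blocks`` lists the true 1-based
    inclusive coordinates of every surviving block instance per gene.
    """
    fspec.validate()
    lib = motif_library or MotifLibrary.default()
    for m in fspec.domain_blocks:
        if m not in lib:
            raise ValueError(f"motif {m!r} missing from motif library")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    def linker(n: int) -> list[str]:
        return list(rng.choice(aa, size=n))

    # segment list: ("linker", chars) or ("block", motif_id, chars)
    root_segments: list[tuple] = [("linker", linker(root_linker_length))]
    for m in fspec.domain_blocks:
        root_segments.append(("block", m,
                              family_root_block(fspec.family_name, m, lib)))
        root_segments.append(("linker", linker(root_linker_length)))

    def substitute(chars: list[str], p: float) -> list[str]:
        if p <= 0 or not chars:
            return chars
        arr = np.array(chars)
        mask = rng.random(len(arr)) < p
        if mask.any():
            arr[mask] = rng.choice(aa, size=int(mask.sum()))
        return list(arr)

    sequences: dict[str, str] = {}
    block_rows: list[dict] = []

    def walk(node: TreeNode, segments: list[tuple], depth: float) -> None:
        length = node.length or 0.0
        depth += length
        if length > 0:
            p_core = 1.0 - math.exp(-fspec.site_rate * fspec.core_rate_multiplier * length)
            p_link = 1.0 - math.exp(-fspec.site_rate * fspec.linker_rate_multiplier * length)
            out = []
            for seg in segments:
                if seg[0] == "linker":
                    chars = substitute(list(seg[1]), p_link)
                    new_len = int(rng.poisson(root_linker_length))
                    delta = new_len - len(chars)
                    if delta > 0:
                        for _ in range(delta):
                            pos = int(rng.integers(0, len(chars) + 1))
                            chars.insert(pos, str(rng.choice(aa)))
                    elif delta < 0:
                        for _ in range(-delta):
                            chars.pop(int(rng.integers(0, len(chars))))
                    out.append(("linker", chars))
                else:
                    out.append(("block", seg[1], substitute(list(seg[2]), p_core)))
            segments = out
        else:
            segments = [(s[0], list(s[1])) if s[0] == "linker"
                        else ("block", s[1], list(s[2])) for s in segments]

        if node.is_tip():
            p_loss = 1.0 - math.exp(-fspec.block_loss_rate * depth)
            pos = 1
            parts = []
            for seg in segments:
                if seg[0] == "block" and rng.random() < p_loss:
                    continue  # whole-block deletion on this terminal lineage
                chars = seg[1] if seg[0] == "linker" else seg[2]
                if seg[0] == "block":
                    block_rows.append({"gene_id": node.name, "motif_id": seg[1],
                                       "start": pos, "end": pos + len(chars) - 1})
                parts.append("".join(chars))
                pos += len(chars)
            sequences[node.name] = "".join(parts)
        else:
            for child in node.children:
                walk(child, segments, depth)

    walk(gene_tree, root_segments, 0.0)
    blocks = pd.DataFrame(block_rows, columns=["gene_id", "motif_id", "start", "end"])
    return sequences, blocks


# ---------------------------------------------------------------------------
# full simulation and fixture I/O
# ---------------------------------------------------------------------------

@dataclass
class FamilyResult:
    spec: FamilySpec
    gene_tree: TreeNode | None
    events: EventLog
    sequences: dict[str, str]
    blocks: pd.DataFrame


@dataclass
class SimulationResult:
    """Everything one simulation produced, ready to write or analyse."""

    species_spec: SpeciesTreeSpec
    family_specs: list[FamilySpec]
    seed: int
    species_tree: TreeNode
    taxonomy: pd.DataFrame
    motifs: MotifLibrary
    families: dict[str, FamilyResult]
    background: dict[str, dict[str, str]]  # species -> {gene_id: sequence}
    root_linker_length: int = 15

    # -- convenience views -------------------------------------------------
    def proteome_records(self) -> list[tuple[str, str, str, str]]:
        """(gene_id, species_id, family_truth, sequence), sorted by gene id."""
        rows = []
        for fam, res in self.families.items():
            for gid, seq in res.sequences.items():
                rows.append((gid, res.events.genes[gid], fam, seq))
        for sp, genes in self.background.items():
            for gid, seq in genes.items():
                rows.append((gid, sp, "none", seq))
        return sorted(rows)

    def truth_families(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "species_id": s, "family": f}
                for g, s, f, _ in self.proteome_records() if f != "none"]
        return pd.DataFrame(rows, columns=["gene_id", "species_id", "family"])

    # -- persistence -------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_newick(self.species_tree, out / "species_tree.nwk")
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        self.motifs.to_frame().to_csv(out / "motifs.tsv", sep="\t", index=False)
        with open(out / "proteomes.fasta", "w") as fh:
            for gid, sp, fam, seq in self.proteome_records():
                fh.write(f">{gid}|{sp}|{fam}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        all_blocks = []
        for fam in sorted(self.families):
            res = self.families[fam]
            if res.gene_tree is not None:
                _write_newick(res.gene_tree, out / f"genetree_{fam}.nwk")
            (out / f"events_{fam}.json").write_text(res.events.to_json())
            all_blocks.append(res.blocks)
        blocks = pd.concat(all_blocks, ignore_index=True) if all_blocks else \
            pd.DataFrame(columns=["gene_id", "motif_id", "start", "end"])
        blocks.to_csv(out / "blocks.tsv", sep="\t", index=False)
        config = {
            "seed": self.seed,
            "root_linker_length": self.root_linker_length,
            "species_spec": {
                "seed": self.species_spec.seed,
                "clade_plan": [asdict(c) for c in self.species_spec.clade_plan],
            },
            "family_specs": [_fspec_to_dict(f) for f in self.family_specs],
        }
        (out / "config.json").write_text(json.dumps(config, indent=1, sort_keys=True))


def _fspec_to_dict(f: FamilySpec) -> dict:
    d = asdict(f)
    d["domain_blocks"] = list(f.domain_blocks)
    d["egt_events"] = [asdict(e) for e in f.egt_events]
    return d


def _fspec_from_dict(d: dict) -> FamilySpec:
    d = dict(d)
    d["egt_events"] = tuple(EgtEvent(**e) for e in d["egt_events"])
    d["domain_blocks"] = tuple(d["domain_blocks"])
    return FamilySpec(**d)


def _write_newick(tree: TreeNode, path: Path) -> None:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    path.write_text(buf.getvalue())


def read_newick(path: str | Path) -> TreeNode:
    with open(path) as fh:
        return TreeNode.read(fh, format="newick", convert_underscores=False)


@dataclass
class Fixture:
    """A simulation re-read from disk (the downstream modules' input form)."""

    species_tree: TreeNode
    taxonomy: pd.DataFrame
    motifs: MotifLibrary
    proteins: list[tuple[str, str, str, str]]  # gene, species, family_truth, seq
    gene_trees: dict[str, TreeNode]
    events: dict[str, EventLog]
    blocks: pd.DataFrame
    config: dict

    @classmethod
    def read(cls, indir: str | Path) -> "Fixture":
        d = Path(indir)
        species_tree = read_newick(d / "species_tree.nwk")
        taxonomy = pd.read_csv(d / "taxonomy.tsv", sep="\t")
        motifs = MotifLibrary.from_frame(pd.read_csv(d / "motifs.tsv", sep="\t"))
        proteins = []
        from Bio import SeqIO
        for rec in SeqIO.parse(str(d / "proteomes.fasta"), "fasta"):
            gid, sp, fam = rec.id.split("|")
            proteins.append((gid, sp, fam, str(rec.seq)))
        gene_trees, events = {}, {}
        for ev_path in sorted(d.glob("events_*.json")):
            fam = ev_path.stem.split("_", 1)[1]
            events[fam] = EventLog.from_json(ev_path.read_text())
            tree_path = d / f"genetree_{fam}.nwk"
            if tree_path.exists():
                gene_trees[fam] = read_newick(tree_path)
        blocks = pd.read_csv(d / "blocks.tsv", sep="\t")
        config = json.loads((d / "config.json").read_text()) \
            if (d / "config.json").exists() else {}
        return cls(species_tree, taxonomy, motifs, proteins, gene_trees,
                   events, blocks, config)


def run_simulation(species_spec: SpeciesTreeSpec,
                   family_specs: Sequence[FamilySpec],
                   seed: int,
                   root_linker_length: int = 15,
                   motif_library: MotifLibrary | None = None,
                   n_background: int = 5,
                   ) -> SimulationResult:
    """Run the full generator: species tree, families, sequences, decoys.

    Per-family random streams are derived from the root seed with
    ``numpy.random.SeedSequence`` spawning, so adding a family does not
    perturb the others.  ``n_background`` unrelated random proteins are
    added per species to give homology searches realistic negatives.
    """
    lib = motif_library or MotifLibrary.default()
    ss = np.random.SeedSequence(seed)
    tree_seed, bg_seed, *fam_seeds = [int(s.generate_state(1)[0] % (2**31))
                                      for s in ss.spawn(2 + len(family_specs))]
    species_spec = SpeciesTreeSpec(clade_plan=species_spec.clade_plan, seed=tree_seed) \
        if species_spec.seed is None else species_spec
    species_tree = simulate_species_tree(species_spec)
    taxonomy = taxonomy_table(species_tree)

    families: dict[str, FamilyResult] = {}
    for fspec, fs in zip(family_specs, fam_seeds):
        gtree, log = simulate_family(species_tree, fspec, seed=fs)
        if gtree is not None:
            seqs, blocks = evolve_sequences(gtree, fspec, root_linker_length,
                                            seed=fs + 1, motif_library=lib)
        else:
            seqs, blocks = {}, pd.DataFrame(columns=["gene_id", "motif_id", "start", "end"])
        families[fspec.family_name] = FamilyResult(fspec, gtree, log, seqs, blocks)

    rng = np.random.default_rng(bg_seed)
    aa = np.array(list(AMINO_ACIDS))
    background: dict[str, dict[str, str]] = {}
    for sp in sorted(t.name for t in species_tree.tips()):
        genes = {}
        for i in range(n_background):
            n = int(rng.integers(150, 301))
            genes[f"bg_{sp}_{i + 1:02d}"] = "".join(rng.choice(aa, size=n))
        background[sp] = genes

    return SimulationResult(species_spec, list(family_specs), seed, species_tree,
                            taxonomy, lib, families, background, root_linker_length)


# ---------------------------------------------------------------------------
# the default study conditions
# ---------------------------------------------------------------------------

DEFAULT_CLADE_PLAN = (
    CladePlan("alpha", "Bacteria", 10, 0.4),
    CladePlan("gamma", "Bacteria", 10, 0.4),
    CladePlan("terra", "Bacteria", 10, 0.2),
    CladePlan("cyano", "Bacteria", 10, 0.0),
    CladePlan("fcb", "Bacteria", 10, 0.2),
    CladePlan("pvc", "Bacteria", 10, 0.0),
    CladePlan("viridiplantae", "Eukaryota", 6, 0.0),
    CladePlan("opisthokonta", "Eukaryota", 6, 0.0),
    CladePlan("euryarchaeota", "Archaea", 2, 0.0),
)

#: scripted donors of the eukaryotic copies, one EGT per family into the
#: eukaryote stem branch midway along its interval.
DEFAULT_EGT_TIME = 0.30
DEFAULT_DONORS = {"MPP": "alpha", "OOP": "gamma", "PreP": "terra", "SPP": "fcb"}


def default_family_specs(site_rate: float = 0.3, block_loss_rate: float = 0.05,
                         ) -> list[FamilySpec]:
    def egt(fam):
        return (EgtEvent(DEFAULT_DONORS[fam], "stem:Eukaryota", DEFAULT_EGT_TIME),)

    common = dict(core_rate_multiplier=0.3, linker_rate_multiplier=1.0,
                  site_rate=site_rate, block_loss_rate=block_loss_rate)
    return [
        FamilySpec("MPP", DEFAULT_COMPOSITIONS["MPP"], dup_rate=0.15, loss_rate=0.08,
                   hgt_rate=0.05, egt_events=egt("MPP"), **common),
        FamilySpec("PreP", DEFAULT_COMPOSITIONS["PreP"], dup_rate=0.05, loss_rate=0.3,
                   hgt_rate=0.05, egt_events=egt("PreP"), **common),
        FamilySpec("SPP", DEFAULT_COMPOSITIONS["SPP"], dup_rate=0.05, loss_rate=0.2,
                   hgt_rate=0.05, egt_events=egt("SPP"), **common),
        FamilySpec("OOP", DEFAULT_COMPOSITIONS["OOP"], dup_rate=0.25, loss_rate=0.12,
                   hgt_rate=0.05, egt_events=egt("OOP"), **common),
    ]


def default_simulation(seed: int = 0, site_rate: float = 0.3,
                       block_loss_rate: float = 0.05, **kwargs) -> SimulationResult:
    """The standard fixture: 60 bacteria in 6 clades, 12 eukaryotes, 2 archaea,
    the four peptidase families each introduced into eukaryotes by one EGT."""
    spec = SpeciesTreeSpec(clade_plan=DEFAULT_CLADE_PLAN, seed=seed)
    fams = default_family_specs(site_rate=site_rate, block_loss_rate=block_loss_rate)
    return run_simulation(spec, fams, seed=seed, **kwargs)
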