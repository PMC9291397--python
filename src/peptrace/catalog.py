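"""Family reconstruction: seeded search, clustered profiles, composition filter.

The cataloguing procedure mirrors standard remote-homolog detection
practice: a reference peptidase is searched against all proteomes, the
hits are clustered by clade, one profile HMM is built per cluster, the
profiles re-scan the proteomes to recover remote homologs, and finally the
candidates are kept as homologs of a family only when their domain-motif
multiset contains everything the family architecture requires (the
mitochondrial processing peptidase needs M16 + M16C, the stromal
processing peptidase needs a second M16C copy, the presequence protease an
additional M16C-associated domain, and the organellar oligo-peptidase the
M3 domain).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import _hmm


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry."""

    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"{self.gene_id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One motif instance on a protein (1-based inclusive coordinates)."""

    motif_id: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid domain coordinates")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class SeedHit:
    gene_id: str
    species_id: str
    evalue: float
    coverage: float
    score: float


@dataclass
class ScanHit:
    """Best profile evidence for one candidate protein."""

    record: ProteinRecord
    profile: str
    evalue: float
    coverage: float


@dataclass(frozen=True)
class FamilyComposition:
    family_name: str
    required_motifs: tuple[str, ...]

    def __post_init__(self):
        if not self.required_motifs:
            raise ValueError("required_motifs must be nonempty")

    @property
    def multiset(self) -> Counter:
        return Counter(self.required_motifs)


def records_from_fixture(proteins: Iterable[tuple[str, str, str, str]]
                         ) -> list[ProteinRecord]:
    """Convert (gene, species, family_truth, seq) tuples into ProteinRecords."""
    return [ProteinRecord(g, s, seq) for g, s, _fam, seq in proteins]


# ---------------------------------------------------------------------------
# seeded similarity search
# ---------------------------------------------------------------------------

def seed_search(reference: ProteinRecord,
                proteomes: Sequence[ProteinRecord],
                min_coverage: float = 0.70,
                max_evalue: float = 1e-5) -> list[SeedHit]:
    """Search the reference peptidase against all proteomes.

    A hit is kept when its E-value is at most ``max_evalue`` and its
    alignment covers at least ``min_coverage`` of the reference (query)
    sequence.  Coverage is measured on the query, i.e. the fraction of
    reference positions included in the local alignment envelope.
    """
    if not proteomes:
        return []
    by_id = {p.gene_id: p for p in proteomes}
    targets = [(p.gene_id, p.sequence) for p in proteomes]
    out: list[SeedHit] = []
    for _qname, hits in _hmm.phmmer_search([(reference.gene_id, reference.sequence)],
                                           targets):
        for hit in hits:
            if hit.evalue > max_evalue:
                continue
            cov = _hmm.query_coverage(hit, reference.length)
            if cov < min_coverage:
                continue
            rec = by_id[_hmm.as_str(hit.name)]
            out.append(SeedHit(rec.gene_id, rec.species_id,
                               float(hit.evalue), cov, float(hit.score)))
    return sorted(out, key=lambda h: (h.evalue, h.gene_id))


# ---------------------------------------------------------------------------
# clade clustering
# ---------------------------------------------------------------------------

def _clade_distance(tree: TreeNode, a: str, b: str) -> int:
    """Topological distance (edge count) between two clade leaves."""
    na, nb = tree.find(a), tree.find(b)
    anc_a = [na] + list(na.ancestors())
    depth = {id(n): i for i, n in enumerate(anc_a)}
    steps = 0
    node = nb
    while id(node) not in depth:
        node = node.parent
        steps += 1
    return steps + depth[id(node)]


def cluster_hits(hits: Sequence[SeedHit],
                 clade_of_species: Mapping[str, str],
                 clade_tree: TreeNode,
                 min_cluster_size: int = 5) -> dict[str, list[SeedHit]]:
    """Partition hits by clade, merging small clusters into sister clades.

    Any cluster with fewer than ``min_cluster_size`` hits is merged with the
    nearest sister cluster on the clade tree (topological distance; ties
    broken alphabetically by cluster name), repeating until every cluster
    reaches the minimum or only one cluster remains.  A merged cluster is
    named by joining its member clades with ``+``.
    """
    clusters: dict[frozenset, list[SeedHit]] = {}
    for h in hits:
        if h.species_id not in clade_of_species:
            raise KeyError(f"species {h.species_id!r} missing from taxonomy")
        clade = clade_of_species[h.species_id]
        clusters.setdefault(frozenset([clade]), []).append(h)

    def name(key: frozenset) -> str:
        return "+".join(sorted(key))

    def dist(k1: frozenset, k2: frozenset) -> int:
        return min(_clade_distance(clade_tree, a, b) for a in k1 for b in k2)

    while len(clusters) > 1:
        small = sorted((k for k, v in clusters.items() if len(v) < min_cluster_size),
                       key=lambda k: (len(clusters[k]), name(k)))
        if not small:
            break
        k = small[0]
        others = [o for o in clusters if o is not k]
        best = min(others, key=lambda o: (dist(k, o), name(o)))
        merged = k | best
        merged_hits = clusters.pop(k) + clusters.pop(best)
        clusters[merged] = merged_hits
    return {name(k): sorted(v, key=lambda h: h.gene_id) for k, v in
            sorted(clusters.items(), key=lambda kv: name(kv[0]))}


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """A position-specific scoring model over one hit cluster."""

    name: str
    hmm: object  # plan7.HMM
    n_sequences: int
    degenerate: bool = False

    @property
    def length(self) -> int:
        return self.hmm.M

    @property
    def consensus(self) -> str:
        return self.hmm.consensus.upper()

    def to_bytes(self) -> bytes:
        import io
        buf = io.BytesIO()
        self.hmm.write(buf)
        return buf.getvalue()

    @classmethod
    def from_bytes(cls, name: str, data: bytes, n_sequences: int = 0) -> "Profile":
        import io
        from pyhmmer import plan7
        hmm = next(plan7.HMMFile(io.BytesIO(data)))
        return cls(name, hmm, n_sequences, degenerate=n_sequences <= 1)


def build_profile(name: str, sequences: Sequence[tuple[str, str]]) -> Profile:
    """Build a profile HMM from a cluster of homologous sequences.

    The longest member anchors a single-sequence profile; all members are
    aligned to it and the resulting multiple alignment is turned into the
    final profile.  A single-sequence cluster yields a degenerate profile,
    flagged as such.
    """
    if not sequences:
        raise ValueError("empty cluster")
    if len(sequences) == 1:
        gid, seq = sequences[0]
        hmm = _hmm.build_hmm_from_sequence(name, seq)
        return Profile(name, hmm, 1, degenerate=True)
    anchor = max(sequences, key=lambda x: (len(x[1]), x[0]))
    anchor_hmm = _hmm.build_hmm_from_sequence(f"{name}.anchor", anchor[1])
    msa = _hmm.align_to_hmm(anchor_hmm, sequences)
    hmm = _hmm.build_hmm_from_msa(name, msa)
    return Profile(name, hmm, len(sequences))


def profile_scan(profiles: Sequence[Profile],
                 proteomes: Sequence[ProteinRecord],
                 max_evalue: float = 1e-2,
                 min_profile_coverage: float = 0.70) -> dict[str, ScanHit]:
    """Scan all proteomes with the cluster profiles.

    A protein becomes a candidate when, for at least one profile, its
    E-value is at most ``max_evalue`` and the alignment covers more than
    ``min_profile_coverage`` of that profile's match states.  The best
    (lowest-E-value) qualifying profile is recorded per candidate.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    by_id = {p.gene_id: p for p in proteomes}
    targets = [(p.gene_id, p.sequence) for p in proteomes]
    best: dict[str, ScanHit] = {}
    for pname, hits in _hmm.hmmsearch_many([p.hmm for p in profiles], targets):
        plen = next(p.length for p in profiles if p.name == pname)
        for hit in hits:
            if hit.evalue > max_evalue:
                continue
            cov = _hmm.query_coverage(hit, plen)
            if cov <= min_profile_coverage:
                continue
            gid = _hmm.as_str(hit.name)
            cur = best.get(gid)
            if cur is None or hit.evalue < cur.evalue:
                best[gid] = ScanHit(by_id[gid], pname, float(hit.evalue), cov)
    return dict(sorted(best.items()))


# ---------------------------------------------------------------------------
# domain annotation and the composition filter
# ---------------------------------------------------------------------------

def _resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy non-overlap resolution per motif, by descending score."""
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.start)):
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda x: x.start)


def annotate_domains(candidates: Sequence[ProteinRecord],
                     motif_models: Mapping[str, str],
                     max_evalue: float = 1e-2) -> dict[str, list[DomainHit]]:
    """Locate the motifs of interest on each candidate.

    ``motif_models`` maps motif id to its consensus sequence (a profile is
    built per motif).  Domain hits with an independent E-value at most
    ``max_evalue`` are kept; overlapping hits of the same motif are resolved
    greedily by descending score.  Returns hits sorted by start coordinate.
    """
    if not candidates:
        return {}
    hmms = [_hmm.build_hmm_from_sequence(m, s) for m, s in sorted(motif_models.items())]
    targets = [(c.gene_id, c.sequence) for c in candidates]
    raw: dict[str, list[DomainHit]] = {c.gene_id: [] for c in candidates}
    for motif_id, hits in _hmm.hmmsearch_many(hmms, targets):
        for hit in hits:
            if hit.evalue > max_evalue:
                continue
            for dom in hit.domains:
                if dom.i_evalue > max_evalue:
                    continue
                ali = dom.alignment
                raw[_hmm.as_str(hit.name)].append(
                    DomainHit(motif_id, int(ali.target_from), int(ali.target_to),
                              float(dom.score), float(dom.i_evalue)))
    out = {}
    for gid, hits in raw.items():
        per_motif: dict[str, list[DomainHit]] = {}
        for h in hits:
            per_motif.setdefault(h.motif_id, []).append(h)
        resolved = [h for m in sorted(per_motif) for h in _resolve_overlaps(per_motif[m])]
        out[gid] = sorted(resolved, key=lambda x: (x.start, x.motif_id))
    return out


def filter_by_composition(candidates: Mapping[str, ScanHit],
                          domain_hits: Mapping[str, list[DomainHit]],
                          compositions: Sequence[FamilyComposition]) -> pd.DataFrame:
    """Keep candidates whose motif multiset contains a family's requirement.

    Multiplicity-aware: a family requiring the M16C-like motif twice is only
    satisfied by two non-overlapping M16C hits.  A candidate satisfying
    several compositions is reported under each, with the largest required
    multiset flagged as ``primary`` (ties broken alphabetically).  The
    output table has one row per (gene, family) assignment.
    """
    rows = []
    for gid in sorted(candidates):
        scan = candidates[gid]
        hits = domain_hits.get(gid, [])
        motif_counts = Counter(h.motif_id for h in hits)
        satisfied = [c for c in compositions
                     if all(motif_counts[m] >= k for m, k in c.multiset.items())]
        if not satisfied:
            continue
        primary = max(satisfied, key=lambda c: (len(c.required_motifs),
                                                [-ord(x) for x in c.family_name]))
        for comp in satisfied:
            rows.append({
                "gene_id": gid,
                "species_id": scan.record.species_id,
                "family": comp.family_name,
                "primary": int(comp is primary),
                "motifs": ";".join(f"{h.motif_id}:{h.start}-{h.end}" for h in hits),
                "best_evalue": scan.evalue,
                "coverage": scan.coverage,
            })
    return pd.DataFrame(rows, columns=["gene_id", "species_id", "family", "primary",
                                       "motifs", "best_evalue", "coverage"])


def family_summary(homologs: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-family, per-domain-of-life homolog and species counts."""
    merged = homologs.merge(taxonomy[["species_id", "domain_of_life"]], on="species_id")
    g = merged.groupby(["family", "domain_of_life"])
    out = g.agg(n_proteins=("gene_id", "nunique"),
                n_species=("species_id", "nunique")).reset_index()
    return out.sort_values(["family", "domain_of_life"]).reset_index(drop=True)


def catalog_additional_domains(homologs: pd.DataFrame,
                               proteins: Mapping[str, ProteinRecord],
                               full_motif_db: Mapping[str, str],
                               compositions: Sequence[FamilyComposition],
                               max_evalue: float = 1e-5) -> pd.DataFrame:
    """Motifs beyond each homolog's family requirement, with sharing counts.

    The full motif database is scanned at a stricter threshold; for every
    homolog the required multiset of its primary family is subtracted and
    whatever remains is an "additional" domain.  ``n_species_sharing``
    counts, per (family, motif), the species in which the extra motif
    occurs on at least one homolog.
    """
    comp_by_name = {c.family_name: c.multiset for c in compositions}
    primaries = homologs[homologs["primary"] == 1]
    records = [proteins[g] for g in primaries["gene_id"] if g in proteins]
    hits = annotate_domains(records, full_motif_db, max_evalue=max_evalue)
    rows = []
    for _, row in primaries.iterrows():
        required = comp_by_name[row["family"]]
        counts = Counter(h.motif_id for h in hits.get(row["gene_id"], []))
        extra = counts - required
        for motif, k in sorted(extra.items()):
            rows.append({"gene_id": row["gene_id"], "species_id": row["species_id"],
                         "family": row["family"], "motif_id": motif, "count": k})
    extras = pd.DataFrame(rows, columns=["gene_id", "species_id", "family",
                                         "motif_id", "count"])
    if extras.empty:
        extras["n_species_sharing"] = pd.Series(dtype=int)
        return extras
    sharing = extras.groupby(["family", "motif_id"])["species_id"].nunique() \
        .rename("n_species_sharing").reset_index()
    return extras.merge(sharing, on=["family", "motif_id"])


# ---------------------------------------------------------------------------
# sample set
# ---------------------------------------------------------------------------

def sample_set(homologs: pd.DataFrame,
               taxonomy: pd.DataFrame,
               groups: str | Mapping[str, str] = "clade",
               forced_species: Sequence[str] = (),
               seed: int = 0) -> tuple[list[str], pd.DataFrame]:
    """Reduce the homolog table to a taxonomically balanced species sample.

    One species with homologs is drawn uniformly at random per taxonomic
    group, plus one per AMP-resistant genus, plus all ``forced_species``;
    every homolog of a selected species is retained.  Empty groups are
    skipped with a warning.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    tax = taxonomy.set_index("species_id")
    with_homologs = set(homologs["species_id"])
    if isinstance(groups, str):
        group_of = tax[groups].to_dict()
    else:
        group_of = dict(groups)

    selected: set[str] = set()
    for group in sorted(set(group_of.values())):
        members = sorted(sp for sp, g in group_of.items()
                         if g == group and sp in with_homologs)
        if not members:
            warnings.warn(f"group {group!r} has no species with homologs; skipped")
            continue
        selected.add(members[int(rng.integers(len(members)))])
    if "resistant" in tax.columns and "genus" in tax.columns:
        resistant = tax[tax["resistant"] == 1]
        for genus in sorted(resistant["genus"].unique()):
            members = sorted(sp for sp in resistant[resistant["genus"] == genus].index
                             if sp in with_homologs)
            if members:
                selected.add(members[int(rng.integers(len(members)))])
    selected.update(forced_species)
    reduced = homologs[homologs["species_id"].isin(selected)].reset_index(drop=True)
    return sorted(selected), reduced


# ---------------------------------------------------------------------------
# end-to-end reconstruction
# ---------------------------------------------------------------------------

@dataclass
class CatalogResult:
    seed_hits: dict[str, list[SeedHit]]
    clusters: dict[str, dict[str, list[SeedHit]]]
    profiles: dict[str, list[Profile]]
    candidates: dict[str, ScanHit]
    domain_hits: dict[str, list[DomainHit]]
    homologs: pd.DataFrame


def reconstruct_families(proteomes: Sequence[ProteinRecord],
                         references: Mapping[str, ProteinRecord],
                         compositions: Sequence[FamilyComposition],
                         motif_models: Mapping[str, str],
                         clade_of_species: Mapping[str, str],
                         clade_tree: TreeNode,
                         seed_min_coverage: float = 0.70,
                         seed_max_evalue: float = 1e-5,
                         scan_max_evalue: float = 1e-2,
                         scan_min_coverage: float = 0.70,
                         domain_max_evalue: float = 1e-2,
                         min_cluster_size: int = 5) -> CatalogResult:
    """Run the complete catalogue pipeline over a proteome collection."""
    seed_hits, clusters, profiles = {}, {}, {}
    all_profiles: list[Profile] = []
    seq_of = {p.gene_id: p.sequence for p in proteomes}
    for fam in sorted(references):
        hits = seed_search(references[fam], proteomes,
                           min_coverage=seed_min_coverage,
                           max_evalue=seed_max_evalue)
        seed_hits[fam] = hits
        if not hits:
            clusters[fam], profiles[fam] = {}, []
            continue
        cl = cluster_hits(hits, clade_of_species, clade_tree,
                          min_cluster_size=min_cluster_size)
        clusters[fam] = cl
        profs = [build_profile(f"{fam}|{cname}",
                               [(h.gene_id, seq_of[h.gene_id]) for h in chits])
                 for cname, chits in cl.items()]
        profiles[fam] = profs
        all_profiles.extend(profs)

    candidates = profile_scan(all_profiles, proteomes,
                              max_evalue=scan_max_evalue,
                              min_profile_coverage=scan_min_coverage) \
        if all_profiles else {}
    needed = {m for c in compositions for m in c.required_motifs}
    missing = needed - set(motif_models)
    if missing:
        raise ValueError(f"compositions name unknown motifs: {sorted(missing)}")
    domain_hits = annotate_domains([c.record for c in candidates.values()],
                                   {m: motif_models[m] for m in sorted(needed)},
                                   max_evalue=domain_max_evalue)
    homologs = filter_by_composition(candidates, domain_hits, compositions)
    return CatalogResult(seed_hits, clusters, profiles, candidates,
                         domain_hits, homologs)


def default_compositions() -> list[FamilyComposition]:
    from .simulate import DEFAULT_COMPOSITIONS
    return [FamilyComposition(f, tuple(m)) for f, m in sorted(DEFAULT_COMPOSITIONS.items())]
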