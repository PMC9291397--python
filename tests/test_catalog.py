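"""Catalogue reconstruction: search thresholds, clustering, composition filter."""

from __future__ import annotations

import collections
import io
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from peptrace import catalog, phylo, pipeline
from peptrace.catalog import (DomainHit, FamilyComposition, ProteinRecord,
                              ScanHit, SeedHit, annotate_domains,
                              build_profile, catalog_additional_domains,
                              cluster_hits, filter_by_composition,
                              profile_scan, sample_set, seed_search)
from peptrace.simulate import (CladePlan, FamilySpec, SpeciesTreeSpec,
                               run_simulation)

RNG = np.random.default_rng(77)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(gid, sp, n=200):
    return ProteinRecord(gid, sp, "".join(RNG.choice(AA, size=n)))


# ---------------------------------------------------------------------------
# seed search
# ---------------------------------------------------------------------------

class TestSeedSearch:
    def test_self_hit_and_decoy(self, small_sim):
        fam = small_sim.families["MPP"]
        gid = sorted(fam.sequences)[0]
        ref = ProteinRecord(gid, fam.events.genes[gid], fam.sequences[gid])
        decoy = random_protein("decoy", "spX", 250)
        copy = ProteinRecord("copy", "spY", ref.sequence)
        hits = seed_search(ref, [copy, decoy])
        ids = {h.gene_id for h in hits}
        assert "copy" in ids and "decoy" not in ids
        h = next(h for h in hits if h.gene_id == "copy")
        assert h.coverage == pytest.approx(1.0)
        assert h.evalue < 1e-20

    def test_empty_proteome_set(self, small_sim):
        fam = small_sim.families["MPP"]
        gid = sorted(fam.sequences)[0]
        ref = ProteinRecord(gid, fam.events.genes[gid], fam.sequences[gid])
        assert seed_search(ref, []) == []

    def test_recovers_true_family_members(self, small_sim, small_catalog):
        truth = set(small_sim.families["MPP"].sequences)
        found = {h.gene_id for h in small_catalog.seed_hits["MPP"]}
        assert truth <= found

    def test_monotone_in_thresholds(self, small_sim):
        proteomes = catalog.records_from_fixture(small_sim.proteome_records())
        fam = small_sim.families["MPP"]
        gid = sorted(fam.sequences)[0]
        ref = ProteinRecord(gid, fam.events.genes[gid], fam.sequences[gid])
        strict = {h.gene_id for h in seed_search(ref, proteomes, 0.8, 1e-20)}
        loose = {h.gene_id for h in seed_search(ref, proteomes, 0.5, 1e-3)}
        assert strict <= loose


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def hits_for(clade_counts):
    hits = []
    for clade, n in clade_counts.items():
        for i in range(n):
            hits.append(SeedHit(f"{clade}_{i}", f"sp_{clade}_{i}", 1e-10, 0.9, 50.0))
    species_clade = {h.species_id: h.species_id.split("_")[1] for h in hits}
    return hits, species_clade


class TestClusterHits:
    def test_small_cluster_merges_with_sister(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1)r;"))
        hits, mapping = hits_for({"A": 10, "B": 3})
        out = cluster_hits(hits, mapping, tree)
        assert list(out) == ["A+B"]
        assert len(out["A+B"]) == 13

    def test_all_large_clusters_unchanged(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1)r;"))
        hits, mapping = hits_for({"A": 6, "B": 5})
        out = cluster_hits(hits, mapping, tree)
        assert sorted(out) == ["A", "B"]

    def test_chain_matches_merge_oracle(self):
        # ladder of three clades; oracle replays the declared rule
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2)r;"))
        hits, mapping = hits_for({"A": 2, "B": 2, "C": 10})

        def oracle():
            clusters = {("A",): 2, ("B",): 2, ("C",): 10}
            dist = {frozenset("AB"): 2, frozenset("AC"): 3, frozenset("BC"): 3}

            def d(k1, k2):
                return min(dist[frozenset((a, b))] for a in k1 for b in k2)

            while len(clusters) > 1:
                small = sorted((k for k, v in clusters.items() if v < 5),
                               key=lambda k: (clusters[k], "+".join(sorted(k))))
                if not small:
                    break
                k = small[0]
                rest = [o for o in clusters if o != k]
                best = min(rest, key=lambda o: (d(k, o), "+".join(sorted(o))))
                clusters[tuple(sorted(set(k) | set(best)))] = \
                    clusters.pop(k) + clusters.pop(best)
            return {"+".join(k): v for k, v in clusters.items()}

        out = cluster_hits(hits, mapping, tree)
        assert {k: len(v) for k, v in out.items()} == oracle()

    def test_missing_species_raises(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1)r;"))
        hits, mapping = hits_for({"A": 5})
        mapping.pop(hits[0].species_id)
        with pytest.raises(KeyError, match=hits[0].species_id):
            cluster_hits(hits, mapping, tree)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

class TestProfiles:
    def test_identical_pair_consensus(self):
        seq = "".join(RNG.choice(AA, size=120))
        prof = build_profile("p", [("a", seq), ("b", seq)])
        assert prof.consensus == seq
        assert not prof.degenerate

    def test_single_sequence_flagged_degenerate(self):
        prof = build_profile("p", [("a", "ACDEFGHIKLMNPQRSTVWY" * 5)])
        assert prof.degenerate

    def test_length_within_member_range(self, small_sim, small_catalog):
        seq_of = {g: s for g, _sp, _f, s in small_sim.proteome_records()}
        for fam, cl in small_catalog.clusters.items():
            for prof in small_catalog.profiles[fam]:
                cname = prof.name.split("|", 1)[1]
                members = [len(seq_of[h.gene_id]) for h in cl[cname]]
                assert min(members) <= prof.length <= max(members)

    def test_serialization_round_trip(self):
        seq = "".join(RNG.choice(AA, size=100))
        prof = build_profile("p", [("a", seq), ("b", seq)])
        back = catalog.Profile.from_bytes("p", prof.to_bytes(), 2)
        assert back.length == prof.length
        assert back.consensus == prof.consensus

    def test_profile_ranks_family_member_top(self, small_sim, small_catalog):
        # scanning with MPP profiles, the best-scoring sequence is an MPP gene
        proteomes = catalog.records_from_fixture(small_sim.proteome_records())
        out = profile_scan(small_catalog.profiles["MPP"], proteomes,
                           max_evalue=10, min_profile_coverage=0.0)
        best = min(out.values(), key=lambda s: s.evalue)
        assert best.record.gene_id in small_sim.families["MPP"].sequences


class TestProfileScan:
    def test_consensus_is_candidate(self):
        seq = "".join(RNG.choice(AA, size=150))
        prof = build_profile("p", [("a", seq), ("b", seq)])
        target = ProteinRecord("t", "sp", prof.consensus)
        out = profile_scan([prof], [target])
        assert "t" in out and out["t"].coverage > 0.95

    def test_low_coverage_excluded(self):
        seq = "".join(RNG.choice(AA, size=200))
        prof = build_profile("p", [("a", seq), ("b", seq)])
        half = ProteinRecord("t", "sp", seq[:100])  # covers 0.5 of the profile
        out = profile_scan([prof], [half], min_profile_coverage=0.70)
        assert "t" not in out

    def test_scan_recall_at_least_seed_recall(self, small_sim, small_catalog):
        truth = set(small_sim.families["MPP"].sequences)
        seed_found = truth & {h.gene_id for h in small_catalog.seed_hits["MPP"]}
        scan_found = truth & set(small_catalog.candidates)
        assert len(scan_found) >= len(seed_found)


# ---------------------------------------------------------------------------
# domain annotation
# ---------------------------------------------------------------------------

class TestAnnotateDomains:
    def test_fixture_blocks_found_in_order(self, small_sim, small_catalog):
        blocks = small_sim.families["MPP"].blocks
        hits = small_catalog.domain_hits
        for gene, grp in blocks.groupby("gene_id"):
            if gene not in hits:
                continue
            found = [h for h in hits[gene]]
            for _, row in grp.iterrows():
                match = [h for h in found if h.motif_id == row.motif_id
                         and h.start <= row.end and h.end >= row.start]
                assert match, f"{gene}: {row.motif_id} block not annotated"
            order_true = grp.sort_values("start")["motif_id"].tolist()
            order_found = [h.motif_id for h in sorted(found, key=lambda h: h.start)
                           if h.motif_id in set(order_true)]
            assert order_found[:len(order_true)] == order_true

    def test_scrambled_sequence_no_hits(self, motif_library):
        scrambled = "".join(RNG.permutation(list(motif_library["M16"] * 2)))
        rec = ProteinRecord("s", "sp", scrambled)
        hits = annotate_domains([rec], motif_library.consensus)
        assert hits["s"] == []

    def test_deleted_block_missing(self, motif_library):
        lib = motif_library
        with_both = ProteinRecord("g1", "sp", lib["M16"] + "GGGG" + lib["M16C"])
        only_one = ProteinRecord("g2", "sp", lib["M16"])
        hits = annotate_domains([with_both, only_one], {"M16": lib["M16"],
                                                        "M16C": lib["M16C"]})
        assert {h.motif_id for h in hits["g1"]} == {"M16", "M16C"}
        assert {h.motif_id for h in hits["g2"]} == {"M16"}

    def test_duplicate_motif_yields_two_hits(self, motif_library):
        lib = motif_library
        spp_like = ProteinRecord("g", "sp",
                                 lib["M16"] + "GGGG" + lib["M16C"] + "GGGG" + lib["M16C"])
        hits = annotate_domains([spp_like], {"M16C": lib["M16C"]})
        assert sum(h.motif_id == "M16C" for h in hits["g"]) == 2


# ---------------------------------------------------------------------------
# composition filter
# ---------------------------------------------------------------------------

COMPS = [FamilyComposition("MPP", ("M16", "M16C")),
         FamilyComposition("PreP", ("M16", "M16C", "M16C_assoc")),
         FamilyComposition("SPP", ("M16", "M16C", "M16C")),
         FamilyComposition("OOP", ("M3",))]


def fake_candidates(motif_sets):
    candidates, hits = {}, {}
    for gid, motifs in motif_sets.items():
        rec = ProteinRecord(gid, f"sp_{gid}", "A" * 50)
        candidates[gid] = ScanHit(rec, "p", 1e-10, 0.9)
        hits[gid] = [DomainHit(m, 10 * i + 1, 10 * i + 5, 30.0, 1e-8)
                     for i, m in enumerate(motifs)]
    return candidates, hits


class TestCompositionFilter:
    def test_table1_compositions(self):
        candidates, hits = fake_candidates({"g": ["M16", "M16C"]})
        out = filter_by_composition(candidates, hits, COMPS)
        assert out["family"].tolist() == ["MPP"]

    def test_empty_motifs_no_family(self):
        candidates, hits = fake_candidates({"g": []})
        out = filter_by_composition(candidates, hits, COMPS)
        assert out.empty

    def test_spp_needs_double_m16c(self):
        candidates, hits = fake_candidates({"g": ["M16", "M16C", "M16C"]})
        out = filter_by_composition(candidates, hits, COMPS)
        fams = set(out["family"])
        assert fams == {"MPP", "SPP"}
        assert out[out["primary"] == 1]["family"].tolist() == ["SPP"]

    def test_multi_family_candidate_reported_under_each(self):
        candidates, hits = fake_candidates(
            {"g": ["M16", "M16C", "M16C", "M16C_assoc"]})
        out = filter_by_composition(candidates, hits, COMPS)
        assert set(out["family"]) == {"MPP", "PreP", "SPP"}
        assert out[out["primary"] == 1].shape[0] == 1

    def test_order_independence(self):
        sets = {f"g{i}": m for i, m in enumerate(
            [["M16", "M16C"], ["M3"], ["M16", "M16C", "M16C"]])}
        candidates, hits = fake_candidates(sets)
        out1 = filter_by_composition(candidates, hits, COMPS)
        rev = dict(reversed(list(candidates.items())))
        out2 = filter_by_composition(rev, hits, COMPS)
        pd.testing.assert_frame_equal(out1, out2)

    def test_species_count_never_exceeds_homolog_count(self, small_sim,
                                                       small_catalog):
        summary = catalog.family_summary(small_catalog.homologs,
                                         small_sim.taxonomy)
        assert (summary["n_species"] <= summary["n_proteins"]).all()


# ---------------------------------------------------------------------------
# additional domains
# ---------------------------------------------------------------------------

class TestAdditionalDomains:
    def test_exact_composition_no_extras(self, motif_library):
        lib = motif_library
        rec = ProteinRecord("g", "sp", lib["M16"] + "GGGG" + lib["M16C"])
        homologs = pd.DataFrame([{"gene_id": "g", "species_id": "sp",
                                  "family": "MPP", "primary": 1}])
        out = catalog_additional_domains(homologs, {"g": rec}, lib.consensus,
                                         COMPS)
        assert out.empty

    def test_extra_block_reported(self, motif_library):
        lib = motif_library
        seqs = {f"g{i}": lib["M16"] + "GGGG" + lib["M16C"] + "GGGG" + lib["ZF1"]
                for i in range(3)}
        proteins = {g: ProteinRecord(g, f"sp{i}", s)
                    for i, (g, s) in enumerate(seqs.items())}
        homologs = pd.DataFrame([{"gene_id": g, "species_id": p.species_id,
                                  "family": "MPP", "primary": 1}
                                 for g, p in proteins.items()])
        out = catalog_additional_domains(homologs, proteins, lib.consensus, COMPS)
        assert set(out["motif_id"]) == {"ZF1"}
        # sharing counts equal a brute-force group-by
        brute = out.groupby(["family", "motif_id"])["species_id"].nunique()
        for _, row in out.iterrows():
            assert row["n_species_sharing"] == brute[(row["family"], row["motif_id"])]


# ---------------------------------------------------------------------------
# sample set
# ---------------------------------------------------------------------------

class TestSampleSet:
    @staticmethod
    def toy_tables():
        tax = pd.DataFrame([
            {"species_id": f"s{i}", "domain_of_life": "Bacteria",
             "clade": f"c{i % 3}", "genus": f"g{i % 4}",
             "resistant": int(i % 4 == 0)}
            for i in range(9)])
        hom = pd.DataFrame([{"gene_id": f"h{i}", "species_id": f"s{i}",
                             "family": "MPP", "primary": 1} for i in range(9)])
        return tax, hom

    def test_one_species_per_group(self):
        tax, hom = self.toy_tables()
        tax["resistant"] = 0
        selected, reduced = sample_set(hom, tax, seed=1)
        assert len(selected) == 3
        assert set(reduced["species_id"]) == set(selected)

    def test_determinism(self):
        tax, hom = self.toy_tables()
        assert sample_set(hom, tax, seed=5)[0] == sample_set(hom, tax, seed=5)[0]

    def test_oracle_recomputation(self, small_sim, small_catalog):
        homologs = small_catalog.homologs
        tax = small_sim.taxonomy
        forced = ["greens_01"]
        selected, reduced = sample_set(homologs, tax, forced_species=forced,
                                       seed=3)
        with_hom = set(homologs["species_id"])
        # one per clade with homologs, one per resistant genus with homologs
        for clade in tax["clade"].unique():
            members = set(tax[tax["clade"] == clade]["species_id"]) & with_hom
            if members:
                assert len(members & set(selected)) >= 1
        res = tax[tax["resistant"] == 1]
        for genus in res["genus"].unique():
            members = set(res[res["genus"] == genus]["species_id"]) & with_hom
            if members:
                assert len(members & set(selected)) >= 1
        assert set(forced) <= set(selected)
        # all homologs of every selected species are retained
        expected = homologs[homologs["species_id"].isin(selected)]
        pd.testing.assert_frame_equal(reduced, expected.reset_index(drop=True))

    def test_empty_group_warns(self):
        tax, hom = self.toy_tables()
        hom = hom[hom["species_id"] != "s0"]  # clade c0 loses a member but not all
        tax.loc[tax["species_id"].isin(["s3", "s6"]), "clade"] = "c9"
        hom = hom[~hom["species_id"].isin(["s3", "s6"])]
        with pytest.warns(UserWarning, match="no species with homologs"):
            sample_set(hom, tax, seed=0)


# ---------------------------------------------------------------------------
# homolog table invariants
# ---------------------------------------------------------------------------

def test_homologs_subset_of_candidates(small_catalog):
    assert set(small_catalog.homologs["gene_id"]) <= set(small_catalog.candidates)


def test_zero_divergence_assignment_perfect():
    spec = SpeciesTreeSpec([CladePlan("alpha", "Bacteria", 4),
                            CladePlan("greens", "Eukaryota", 2)], seed=6)
    fams = [FamilySpec("MPP", ("M16", "M16C"), site_rate=0.0,
                       block_loss_rate=0.0),
            FamilySpec("OOP", ("M3",), site_rate=0.0, block_loss_rate=0.0)]
    sim = run_simulation(spec, fams, seed=6, n_background=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pipeline.analyze(sim, k=5)
    scores = pipeline.assignment_scores(res, sim.truth_families())
    assert (scores["precision"] == 1.0).all()
    assert (scores["recall"] == 1.0).all()
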