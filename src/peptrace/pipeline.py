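"""End-to-end analysis: catalogue, trees, proximity, co-occurrence, logos.

Glues the per-module operations into the full workflow so that the command
line, the acceptance script and the determinism tests all run the same
code path.  All outputs are plain TSV/newick and are written in sorted
order, so identical inputs and seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from . import catalog, cooccurrence, motif, phylo, proximity
from .simulate import SimulationResult, DEFAULT_COMPOSITIONS


@dataclass
class PipelineResult:
    catalog: catalog.CatalogResult
    homologs: pd.DataFrame
    trees: dict[str, TreeNode]
    proximity: pd.DataFrame
    pan_top: dict[str, set[str]]
    presence: pd.DataFrame
    enrichment: pd.DataFrame
    misclassified: pd.DataFrame | None
    logo: pd.DataFrame | None
    catalytic: dict[str, list[int]]


def pick_references(sim: SimulationResult) -> dict[str, catalog.ProteinRecord]:
    """One reference peptidase per family, preferring a eukaryotic member
    (the analysis is seeded from the plant peptidases in practice)."""
    dom = sim.taxonomy.set_index("species_id")["domain_of_life"].to_dict()
    refs = {}
    for fam, res in sim.families.items():
        if not res.sequences:
            continue
        genes = sorted(res.sequences)
        euk = [g for g in genes if dom[res.events.genes[g]] == "Eukaryota"]
        gid = euk[0] if euk else genes[0]
        refs[fam] = catalog.ProteinRecord(gid, res.events.genes[gid],
                                          res.sequences[gid])
    return refs


def analyze(sim: SimulationResult,
            k: int = 10,
            compositions=None,
            outdir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline on a simulation and optionally write results."""
    comps = compositions or catalog.default_compositions()
    proteomes = catalog.records_from_fixture(sim.proteome_records())
    records_by_id = {p.gene_id: p for p in proteomes}
    references = pick_references(sim)
    clade_of = sim.taxonomy.set_index("species_id")["clade"].to_dict()
    ctree = phylo.clade_tree_from_species(sim.species_tree, clade_of)
    cat = catalog.reconstruct_families(
        proteomes, references, comps, sim.motifs.consensus, clade_of, ctree)
    homologs = cat.homologs
    primary = homologs[homologs["primary"] == 1]

    dom = sim.taxonomy.set_index("species_id")["domain_of_life"].to_dict()
    trees: dict[str, TreeNode] = {}
    prox_frames = []
    pan_top: dict[str, set[str]] = {}
    comp_by_name = {c.family_name: c.required_motifs for c in comps}
    for fam in sorted(comp_by_name):
        fam_genes = primary[primary["family"] == fam]["gene_id"].tolist()
        if len(fam_genes) < 3:
            continue
        seqs = {g: records_by_id[g].sequence for g in fam_genes}
        aln = phylo.align_family_motifs(seqs, cat.domain_hits, comp_by_name[fam],
                                        sim.motifs.consensus)
        if len(aln.names) < 3:
            continue
        tree = phylo.midpoint_root(phylo.infer_tree(aln))
        trees[fam] = tree
        gene_species = {g: records_by_id[g].species_id for g in aln.names}
        prox = proximity.proximity_table(tree, gene_species, sim.taxonomy, fam,
                                         sequences=seqs)
        if not prox.empty and prox[["dist_E", "dist_T", "dist_S"]].notna().any().any():
            prox_frames.append(prox)
            pan_top[fam] = proximity.pan_top_k(prox, fam, k)
    prox_all = pd.concat(prox_frames, ignore_index=True) if prox_frames else \
        pd.DataFrame(columns=["species_id", "family", "dist_E", "dist_T", "dist_S",
                              "closest_dist_E", "closest_dist_T", "closest_dist_S"])

    presence = cooccurrence.build_presence(primary, sim.taxonomy)
    clades = sorted(sim.taxonomy.loc[sim.taxonomy["domain_of_life"] == "Bacteria",
                                     "clade"].unique())
    enrichment = cooccurrence.enrichment_report(presence, clades=[None, *clades])

    # combined tree over the three M16-family peptidases (shared M16+M16C)
    misclassified = None
    m16_fams = [f for f in ("MPP", "PreP", "SPP") if f in comp_by_name]
    m16_genes = primary[primary["family"].isin(m16_fams)]["gene_id"].tolist()
    if len(m16_genes) >= 3:
        seqs = {g: records_by_id[g].sequence for g in m16_genes}
        aln = phylo.align_family_motifs(seqs, cat.domain_hits, ("M16", "M16C"),
                                        sim.motifs.consensus)
        if len(aln.names) >= 3:
            m16_tree = phylo.midpoint_root(phylo.infer_tree(aln))
            trees["M16_combined"] = m16_tree
            fam_of = primary.set_index("gene_id")["family"].to_dict()
            misclassified = phylo.count_misclassified(
                m16_tree, {t.name: fam_of[t.name] for t in m16_tree.tips()})

    # logo of the M16 motif block in MPP homologs, and the catalytic scan
    logo = None
    catalytic: dict[str, list[int]] = {}
    if "MPP" in comp_by_name:
        mpp_genes = primary[primary["family"] == "MPP"]["gene_id"].tolist()
        if mpp_genes:
            seqs = {g: records_by_id[g].sequence for g in mpp_genes}
            aln = phylo.align_family_motifs(seqs, cat.domain_hits, ("M16",),
                                            sim.motifs.consensus)
            if aln.names:
                logo = motif.stats_table(motif.logo_stats(aln.rows))
            for g in sorted(mpp_genes):
                catalytic[g] = motif.find_catalytic_motif(seqs[g], tolerance=2)

    result = PipelineResult(cat, homologs, trees, prox_all, pan_top, presence,
                            enrichment, misclassified, logo, catalytic)
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.homologs.to_csv(out / "homologs.tsv", sep="\t", index=False)
    result.proximity.to_csv(out / "proximity.tsv", sep="\t", index=False)
    result.presence.to_csv(out / "presence.tsv", sep="\t")
    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    pan_rows = [{"family": f, "species_id": s}
                for f in sorted(result.pan_top) for s in sorted(result.pan_top[f])]
    pd.DataFrame(pan_rows, columns=["family", "species_id"]) \
        .to_csv(out / "pan_top.tsv", sep="\t", index=False)
    for fam in sorted(result.trees):
        import io as _io
        buf = _io.StringIO()
        result.trees[fam].write(buf, format="newick")
        (out / f"tree_{fam}.nwk").write_text(buf.getvalue())
    if result.misclassified is not None:
        result.misclassified.to_csv(out / "misclassified.tsv", sep="\t", index=False)
    if result.logo is not None:
        result.logo.to_csv(out / "logo_MPP_M16.tsv", sep="\t", index=False)
    cat_rows = [{"gene_id": g, "positions": ";".join(map(str, pos))}
                for g, pos in sorted(result.catalytic.items())]
    pd.DataFrame(cat_rows, columns=["gene_id", "positions"]) \
        .to_csv(out / "catalytic_motif.tsv", sep="\t", index=False)


def assignment_scores(homologs: pd.DataFrame | PipelineResult,
                      truth: pd.DataFrame) -> pd.DataFrame:
    """Precision/recall/F1 of primary family assignment against the simulated
    truth (one row per family)."""
    if isinstance(homologs, PipelineResult):
        homologs = homologs.homologs
    primary = homologs[homologs["primary"] == 1]
    pred = primary.set_index("gene_id")["family"].to_dict()
    true = truth.set_index("gene_id")["family"].to_dict()
    rows = []
    for fam in sorted(set(true.values())):
        tp = sum(1 for g, f in pred.items() if f == fam and true.get(g) == fam)
        fp = sum(1 for g, f in pred.items() if f == fam and true.get(g) != fam)
        fn = sum(1 for g, f in true.items() if f == fam and pred.get(g) != fam)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append({"family": fam, "tp": tp, "fp": fp, "fn": fn,
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows)
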