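# peptrace

Tools for tracing the bacterial origins of the peptidases that process and
degrade organelle targeting peptides.

Nuclear-encoded proteins are imported into mitochondria and chloroplasts
via an N-terminal targeting peptide (TP) that is cleaved and degraded
after import by a dedicated proteolytic pathway: the mitochondrial and
stromal processing peptidases (MPP, SPP — MEROPS family M16) release the
mature protein, and the presequence protease and organellar
oligo-peptidase (PreP — M16, OOP — M3) degrade the freed peptide. All four
families are of bacterial descent, and the bacterial lineages whose
homologs sit closest to the eukaryotic copies are candidate donors of the
endosymbiotic gene transfers (EGT) that established the pathway — with a
special interest in bacteria resistant to antimicrobial peptides (AMPs),
since TPs and a class of AMPs are evolutionarily related.

`peptrace` implements the full comparative workflow for researchers in
organelle evolution:

* **catalog** — homolog cataloguing from proteome FASTA: seeded profile
  search (phmmer), clade-clustered profile HMMs, proteome-wide scan, and a
  domain-composition filter (MPP = M16+M16C, PreP = M16+M16C+M16C_assoc,
  SPP = M16+M16C×2, OOP = M3) that separates true homologs from generic
  M16/M3 peptidases;
* **phylo** — motif-concatenated alignments, deterministic
  neighbor-joining gene trees, midpoint rooting, monophyly tests,
  taxon collapsing and misclassification counting;
* **proximity** — per-bacterium distance to the closest eukaryotic
  homolog under three metrics (branch-length sum `dist_E`, internal-node
  count `dist_T`, log10 best E-value `dist_S`), top-k / pan-top-k donor
  selection and rank-sum comparisons of AMP-resistant vs other bacteria;
* **cooccurrence** — species × family presence matrix and exact
  (Fisher-type) co-occurrence enrichment;
* **motif** — sequence-logo column statistics and a scanner for the
  catalytic zinc-binding motif HxxEHx(76)E;
* **simulate** — a gene-family evolution generator (species tree with
  labelled clades; duplication / loss / HGT / scripted EGT; domain-block
  sequences) that provides ground truth for every stage.

## Worked example

```python
from peptrace import pipeline
from peptrace.simulate import default_simulation

sim = default_simulation(seed=42)          # 74 species, 4 families
result = pipeline.analyze(sim, k=10)       # catalogue -> trees -> metrics

scores = pipeline.assignment_scores(result.homologs, sim.truth_families())
print(scores[["family", "precision", "recall", "f1"]].round(3))

pan = result.pan_top["MPP"]
frac = sum(s.startswith("alpha") for s in pan) / len(pan)
print(f"MPP pan-top-10 donor-clade share: {frac:.2f}")
```

prints

```
  family  precision  recall     f1
0    MPP      0.974   0.927  0.950
1    OOP      1.000   0.936  0.967
2   PreP      1.000   0.897  0.946
3    SPP      1.000   0.910  0.953
MPP pan-top-10 donor-clade share: 0.44
```

Family assignment recovers each simulated family with F1 ≥ 0.94 at the
default noise level (0.3 substitutions/site, ~5% block loss per unit
path); the remaining errors are genes whose diagnostic domain block was
genuinely deleted in simulation. The MPP family was scripted to enter
eukaryotes by a single transfer from clade "alpha": alpha species make up
44% of the pan-top-10 closest bacteria versus a ~17% background share, so
the distance metrics point back at the true donor.

A `peptrace` command-line interface wraps the same steps
(`peptrace simulate`, `peptrace analyze`, `peptrace tree`,
`peptrace logo`, `peptrace motif-scan`).

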