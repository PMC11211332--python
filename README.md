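# tcrlineage

TCR-clonotype lineage-trajectory analysis for exhausted CD8⁺ T cell
populations.

In paired single-cell RNA + TCR sequencing, the rearranged T cell receptor
acts as a natural lineage barcode: every cell carrying the same chain,
V gene, J gene and CDR3 nucleotide sequence descends from one ancestral
clone. When cells are also partitioned into transcriptomic clusters, the
set of clusters a clone spans reveals differentiation paths — in
particular, whether two exhausted ("Tex") end states (a PD-1⁺ population
and CD57⁺ populations) arise from a common, less-differentiated precursor.

`tcrlineage` implements that analysis as a reusable, tested pipeline:

- **Clonotype definition and QC.** Clone key = chain + V + J + CDR3 nt.
  Cells are filtered to exactly one productive TRA and one productive TRB
  contig (doublet removal), then intersected with the expression-QC'd cell
  metadata.
- **Clonal expansion.** A cell is expanded when its clone key occurs in
  more than one cell within its scope group (default donor × cluster).
  Per-donor expanded fractions in Tex vs non-exhausted clusters are
  compared with a two-sided equal-variance t-test.
- **Repertoire sharing.** Per-cluster repertoires of unique clone keys;
  pairwise shared counts and Jaccard similarity
  J(X,Y) = |X∩Y| / |X∪Y|; a sharing network (nodes sized by cells with a
  TCR, edges weighted by shared clones, self-loops for within-cluster
  expansion); and a candidate-precursor analysis — the percentage of each
  donor's Tex cells sharing a clone with each candidate cluster, compared
  across candidates with a Kruskal–Wallis test.
- **Trajectory classification.** Each clone's cluster signature S is
  labelled from its intersections with the precursor (P), PD-1⁺ (D₁) and
  CD57⁺ (D₅₇) role sets:
  P∧D₁∧¬D₅₇ → Tex-PD-1⁺; P∧D₅₇∧¬D₁ → Tex-CD57⁺; P∧D₁∧D₅₇ → Tex-Branching;
  ¬P∧D₁∧D₅₇ → Tex-Fluid; otherwise Unassigned. Combination counts (the
  upset decomposition) and per-donor Shannon–Wiener diversity
  H = −Σ pᵢ ln pᵢ complete the picture.
- **Antigen specificity.** Exact matching of chain + V + J + CDR3 amino
  acids to a VDJdb-style table, summarized per epitope species and
  trajectory.
- **Signature scoring.** Any-overlap interval intersection (0-based,
  half-open), peak-set Jaccard with hypergeometric enrichment
  P(X ≥ k), peak-to-gene annotation within ±5 kb of a feature start,
  per-sample aggregate scores over a gene list (e.g. a CD57⁺ Tex
  chromatin-accessibility score), and z-score-adjusted cluster means.
- **Synthetic cohorts.** A generator plants clones with known trajectories
  across a configurable cohort (default 12 donors, 6 responders, clusters
  1–8 with cluster 4 the precursor, 7 the PD-1⁺ Tex and 5/6/8 the CD57⁺
  Tex populations), so every stage is testable against ground truth
  without external data.

## Worked example

```python
import tcrlineage as tl

cfg = tl.SimConfig(seed=1, clones_per_donor=50)
cohort = tl.generate_cohort(cfg)
paired = tl.filter_single_pair_cells(cohort.contigs, cohort.metadata)
print("paired cells:", len(paired))

assigned = tl.classify_all(tl.build_signatures(paired))
print(assigned["label"].value_counts().sort_index().to_string())

prec = tl.precursor_sharing(paired)
print({c: round(m, 1) for c, m in prec.medians.items()})
print("KW H = %.1f, p = %.2e" % (prec.statistic, prec.pvalue))
```

prints

```
paired cells: 2065
label
TexBranching    137
TexCD57         113
TexFluid         53
TexPD1           77
Unassigned      220
{1: 0.0, 2: 0.0, 3: 0.0, 4: 79.4}
KW H = 45.7, p = 6.45e-10
```

2,065 cells pass the single-pair filter (one TRA + one TRB each); their
600 planted clones resolve into the four Tex trajectories plus the
Unassigned class (clones confined to non-exhausted clusters or a single
cluster). The precursor analysis recovers the planted structure: the
median percentage of Tex cells sharing a clone with cluster 4 is 79.4%
versus 0% for clusters 1–3 (Kruskal–Wallis p ≈ 6 × 10⁻¹⁰).

The same stages are available from the shell:

```sh
tcrlineage simulate --seed 1 --out-dir fixtures
tcrlineage filter --contigs fixtures/filtered_contig_annotations.csv \
    --metadata fixtures/cell_metadata.tsv --out paired.tsv
tcrlineage trajectories --paired paired.tsv --out-dir results
tcrlineage run-all --config config.yaml   # everything from one YAML file
```

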