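# Methods

## Clonal identity and filtering

A clonotype is the tuple (chain, V gene, J gene, CDR3 nucleotide
sequence). Nucleotide-level CDR3 identity is stringent enough that a clone
key is effectively private to one donor, which is why all sharing analyses
operate within donor unless explicitly pooled. Gene names are
case-normalized; clone keys are serialized as `CHAIN|V|J|CDR3NT` strings
in all tables.

Cells enter the analysis only if they have exactly one productive TRA and
one productive TRB contig (cells with extra chains are treated as
potential doublets; cells with a missing chain as failed TCR recovery) and
appear in the cell metadata, which is taken to be the expression-QC'd cell
set. Non-productive contigs are removed before the pair count, so a
non-productive second chain does not disqualify a cell. All readers and
filters are loss-accounting: rows in = rows kept + rows dropped, with
per-reason counts in `attrs` and the run log.

## Expansion

A cell is clonally expanded when its clone key occurs in more than one
cell within its scope group. The default scope is donor × cluster;
`scope="cluster"` pools donors (a sensitivity mode — nucleotide clone keys
rarely recur across donors, so the two agree in practice) and
`scope="donor"` pools clusters. The Tex vs non-exhausted comparison
computes per-donor expanded fractions over the cells of each cluster
group (each cell belongs to exactly one cluster, so the groups partition
cells) and applies a two-sided two-sample t-test, equal-variance by
default with a Welch option. When both groups have zero variance the t
statistic is unbounded; the comparison then returns a result flagged
`degenerate_variance` (statistic 0 and p = 1 if the means coincide,
otherwise a signed infinite statistic with p = 0) rather than NaN.

## Sharing and the precursor analysis

Cluster repertoires are sets of unique clone keys; the headline sharing
matrix pools donors (clones are linked across all samples), while a
per-donor variant exists behind a scope switch. Jaccard similarity is
|X∩Y|/|X∪Y|, defined 0 (and logged) when both sets are empty. The sharing
network carries cluster sizes (cells with a sequenced TCR) on nodes,
unique shared-clone counts on edges, and the number of within-cluster
expanded clones as self-loops.

The precursor analysis asks which candidate cluster (default 1–4) shares
the most clones with the Tex compartment (default clusters 5–8): for each
donor and candidate c, the percentage of the donor's Tex cells whose
clone key also occurs in cluster c *of the same donor*, compared across
candidates with a Kruskal–Wallis one-way test. Within-donor evaluation is
a deliberate choice (clone keys are donor-private); a cohort where no
sharing exists at all yields a `no_variation` report instead of a
p-value.

## Trajectory classification

Signatures are per (clone, donor) — the primitive — with pooled
aggregation available. With role sets P (precursor), D₁ (PD-1⁺ Tex) and
D₅₇ (CD57⁺ Tex), the label is a pure function of which roles the
signature touches: P∧D₁∧¬D₅₇ → TexPD1, P∧D₅₇∧¬D₁ → TexCD57,
P∧D₁∧D₅₇ → TexBranching, ¬P∧D₁∧D₅₇ → TexFluid, else Unassigned. Clones
that additionally touch clusters outside all role sets keep their label
and get an `extended` flag — the classification rules mention only the
role clusters, and the flag exposes rather than hides the ambiguity. The
same reasoning applies to TexFluid: absence from non-exhausted clusters
is not required, only absence from the precursor.

The combination decomposition counts each clone once under its full
signature (an exact partition, the input to an upset plot). Shannon–Wiener
diversity H = −Σ pᵢ ln pᵢ is computed per donor per trajectory on cell
counts per clone (abundance-weighted: richness and evenness), in nats by
default with a configurable log base; across-trajectory differences are
tested with Kruskal–Wallis on per-donor H values, requiring at least two
trajectories with at least two donors each.

## Specificity

Annotation matches chain + V + J + CDR3 *amino acids* exactly against a
VDJdb-style export — amino-acid resolution because convergent
recombination makes distinct nucleotide clones share specificity. Allele
suffixes (`*01`) are stripped before matching by default (database and
10x dialects differ); the flag `strip_alleles=False` restores strict
matching. The database is deduplicated first, so row duplication cannot
change results; multiple epitopes of one species collapse to one
annotation, and conflicting species are all reported with an ambiguity
flag.

## Peak-set and gene-set scoring

Coordinates are 0-based half-open throughout; BED input is native. Two
intervals overlap when they share at least one base, so abutting
intervals do not overlap. Peak-set Jaccard counts the intersection from
the query side (|X∩Y| = number of query intervals hitting the subject,
|X∪Y| = |A| + |B| − |X∩Y|); a symmetric variant averages both directions.
Hypergeometric enrichment is the inclusive upper tail P(X ≥ k); the
universe N is always supplied by the caller (for peak overlaps, typically
the consensus-peak count) and never inferred. Peak-to-gene annotation
assigns each peak to the nearest feature (TSS, miRNA or exon) whose start
lies within ±5,000 bp of the peak; the window is symmetric so strand does
not move it, but strand must be present and valid as a schema check. Ties
at equal distance go to the earlier feature row.

The aggregate signature score (e.g. a CD57⁺ Tex chromatin score) is the
per-sample mean of log-normalized scores over the gene list — mean rather
than sum so the score is invariant to gene-list size; sum mode is
available. How duplicate per-gene columns arise (a gene with several
peaks) is left to the caller and logged. Z-score cluster summaries take
per-cluster means per gene, then z-score across clusters with the sample
standard deviation; genes with identical cluster means get an all-zero
row and a flag.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 12 donors (6
responders, 6 non-responders), clusters 1–8 with cluster 4 the planted
common precursor, cluster 7 the PD-1⁺ Tex population and clusters 5, 6, 8
the CD57⁺ Tex populations. Per clone it draws a trajectory label from a
mixture (default 0.12 / 0.18 / 0.25 / 0.10 / 0.35 over TexPD1, TexCD57,
TexBranching, TexFluid, NonTexOnly — Tex-Branching the most abundant Tex
class and a substantial non-exhausted background), an intended cluster
set consistent with the label (Tex labels include every precursor/PD-1⁺
cluster they require plus a uniformly chosen non-empty subset of the
CD57⁺ clusters; NonTexOnly clones span 1–3 non-exhausted clusters with
weights 0.7/0.2/0.1), and a geometric clone size (default p = 0.5,
support ≥ 1; the true clone-size law of real repertoires is unknown, so
the distribution is a configurable stand-in). Sizes smaller than the
intended set are resampled, never silently under-placed; a separate
geometric parameter for NonTexOnly clones allows planting expansion
differences (e.g. mean size 4 Tex clones against non-Tex singletons).
Cells are placed first one per intended cluster, the remainder uniformly,
so the full signature is observable whenever the clone is large enough.

CDR3 nucleotide strings are 24–60 random sense codons, unique per donor
by construction (collisions are redrawn) and cross-donor collisions
negligible at that length; each clone has one fixed TRA and one
clone-linked TRB, so TRB-based replication of any TRA analysis gives
identical flags. Dropout removes whole TCRs per cell by default
(dropped cells stay in the metadata as cells without a sequenced TCR); a
per-chain mode produces single-chain cells that exercise the pair filter.
A fraction of clones can be tagged with a synthetic epitope species
(CMV-weighted) and emitted as a matching VDJdb-style table.

`null_cohort_config()` produces the structure-free reference used for
type-I-error checks: every cluster carries the non-exhausted role and
every clone is NonTexOnly, so clones span random cluster subsets with all
clusters exchangeable — under this null the candidate-precursor groups
are exchangeable by construction and the expansion comparison has no
planted direction.

What the generator does **not** emulate: transcriptome counts (clusters
are labels, not expression), MAIT or other excluded populations, V(D)J
recombination biases, cross-donor public clones, or donor-specific TCR
recovery rates. Passing tests therefore demonstrate correctness of the
set-combinatoric machinery under the planted model, not robustness to
every artefact of real repertoires.

## Determinism and problem sizes

A single integer seed drives every random draw through one
`numpy.random.Generator`; identical configs give byte-identical output
files (tables are emitted in sorted order with a fixed float format, and
the run log carries no timestamps). Test and acceptance runs use cohorts
of roughly 500–2,000 clones (e.g. 12 donors × 167 clones for recovery
checks, 100 × 40-clone-per-donor null cohorts for calibration), sizes at
which mixture frequencies are within three standard errors of their
targets and the whole suite runs in about a minute.

## Known limitations

- The doublet filter cannot distinguish true doublets from cells with a
  genuinely duplicated chain; both are removed.
- Trajectory labels are set-combinatoric, not probabilistic: a single
  stray cell in a cluster changes the signature. Dropout can only shrink
  signatures, so misclassification degrades monotonically toward
  sub-signature classes or Unassigned.
- Pooled sharing matrices mix donors; with nucleotide clone keys this is
  nearly a union over donors, but amino-acid-level convergence is not
  modelled.
- Specificity matching is exact; no edit-distance or MHC-restriction
  logic.
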