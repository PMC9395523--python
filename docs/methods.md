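# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the methodology was
genuinely open.

## Homology search and similarity matrices

Protein pairs are aligned locally (Smith–Waterman) under a named
substitution matrix (default BLOSUM62) with affine gaps. The gap
convention is that a gap of length *k* costs `gap_open + (k−1)·gap_extend`
(defaults 11 / 1); the brute-force dynamic-programming oracle used in the
tests implements the same convention independently. Three summary
statistics are reported per hit: the raw score; percent identity and
percent similarity — positive-scoring residue pairs, i.e. BLAST's
"Positives" — both over all alignment columns including internal gap
columns; and a Karlin–Altschul e-value `E = K·m·n·e^(−λS)` with *m*, *n*
the full sequence lengths and the standard gapped-BLOSUM62 constants
λ = 0.267, K = 0.041. The constants are configurable because exact
e-values are tool- and version-dependent; only the categorical decision
(hit at E ≤ 10⁻¹⁰ or not) feeds downstream analysis.

The proteome-vs-genome search aligns each query against the translated
annotated CDS of the target genome (minus-strand CDS reverse-complemented
before translation, table 11) rather than against six-frame genomic DNA.
On data where every gene is annotated the two are equivalent, and the CDS
route is orders of magnitude cheaper; for externally produced searches
against raw DNA, tabular 12/13-column output can be ingested instead
(`similarity_matrix_from_blast_tab`), with percent identity standing in
for similarity (logged) when the positives column is absent. Best hits
are ranked by raw score, ties broken by higher identity then
lexicographic locus tag. A shared-4-mer prescreen skips subject CDS with
no common 4-mer; at the ≥ 50–60% similarity levels that matter here a
missed homolog would need to share no 4-mer at all, which at these
lengths is vanishingly rare, and the prescreen can be disabled
(`prescreen_k=None`).

Presence/absence calls use two one-sided thresholds: below 50% absent,
above 55% present, between them ambiguous. Ambiguous cells disqualify a
gene from the exclusive lists in either direction — the conservative
reading of a two-threshold scheme. Exclusivity is computed per reference
proteome and should be run in both directions (a group-A reference finds
group-A-exclusive presences; a group-B reference finds group-A-exclusive
absences), since a reference genome cannot query genes it lacks.

## Diagnostic sites

Core families are reference proteins with best-hit similarity ≥ 60% in
every genome. Members (one per genome, the recorded best hit) are
aligned with a deterministic star-progressive aligner: the centre is the
member with the highest mean pairwise score, all others are aligned to it
globally, and gaps are merged under "once a gap, always a gap". For two
sequences this is exactly the optimal global alignment; for the
low-divergence families this module targets, star merging is adequate,
and externally computed alignments can be substituted. A column is
diagnostic iff each group is internally invariant, both consensi are
non-gap, and they differ; any gap anywhere in a column excludes it — the
generalisation of excluding truncated proteins to avoid artefacts.
Reference positions count non-gap reference residues up to the column;
sites where the reference row is gapped are retained but flagged
position-less.

## Ortholog graph

Nodes are genome-qualified proteins; an undirected edge joins two
proteins whose optimal local alignment exceeds the similarity cutoff
(default 60%, percent positives — the same quantity used throughout)
at the e-value cutoff. Because local alignment under a symmetric scoring
table is symmetric, one alignment decides both directions. Connected
components are the ortholog clusters; paralogs may share a cluster, and
downstream counting sums per cluster. Naming sorts components by their
smallest member (genome id, then locus tag) and numbers from 1 —
determinism is the requirement, the numbering itself carries no meaning.
Renamed annotations carry `<cluster>|<original locus tag>` so the
original annotation is recoverable exactly.

## Cross-species differential expression

The counts table holds one RNA-seq sample per species; species is
therefore confounded with biological replicate. The contrast treats
species as independent samples — that is the design being emulated, and
this package documents rather than resolves it.

The model is NB2: `Var(y) = μ + αμ²`, α = 0 the Poisson limit.

1. **Core transcriptome.** Clusters with ≥ 1 read in every sample
   (configurable to > 1; both readings of the filter exist in the
   field's practice and the choice is surfaced as `core_min_count`).
2. **Size factors.** Median-of-ratios: for clusters with all-positive
   counts, each sample's ratio to the cluster's geometric mean; the
   sample's factor is the median ratio.
3. **Dispersions.** Per cluster, a within-group moment estimate
   `α̂ = (s² − μ̄)/μ̄²` on normalised counts (sample-size-weighted across
   the two groups), shrunk toward the panel's trimmed-mean dispersion
   with an empirical-Bayes weight `τ²/(τ² + vᵢ)`: `vᵢ` is the
   delta-method sampling variance of cluster *i*'s moment estimate,
   `2·w_g²/(n_g−1)·(1/μ̄ + ᾱ)²` summed over groups, and `τ²` the
   between-cluster variance of raw estimates in excess of sampling
   noise (floored at 0). A fixed-weight shrinkage was evaluated first;
   its plug-in noise correlates with the Wald denominator and inflates
   the null type-I error to ≈ 0.063 at 10-vs-10, whereas the
   empirical-Bayes weight adapts — collapsing to the common value on
   homogeneous panels (type-I ≈ 0.055–0.06) while retaining per-cluster
   dispersions on heterogeneous ones.
4. **Wald test.** Per cluster, NB log-link regression with design
   (intercept, group indicator) and `log(size factor)` offsets, fitted
   by IRLS (weights `μ/(1+αμ)`, convergence `|Δβ| < 10⁻⁸`, ≤ 100
   iterations; moment start from group means). `log2FC = β̂₁/ln 2`, its
   standard error from the inverse Fisher information, p two-sided from
   the standard normal law on `log2FC/SE`. Non-converged fits are
   flagged and their p left missing, never set to 1. Because the
   dispersion is a plug-in and the reference law is normal rather than
   t, the test is mildly anticonservative at small sample counts
   (measured ≈ 0.055–0.065 at nominal 0.05 with 10 samples per group);
   this is a property of the published model class, not an
   implementation artefact.
5. **BH adjustment.** Step-up `q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j` capped at 1,
   input order preserved, missing p excluded from *m*.

"Bias" of the effect estimator is reported in the statistical sense: the
mean signed error of `l̂og2FC` within each planted-sign class, magnitudes
averaged. Per-cluster absolute error is dominated by sampling noise
(sd ≈ 0.2 log2 units at α = 0.1, 10 vs 10, mean 500) and is not a
property an estimator can drive to zero.

## ANI

ANIb conventions: the query genome is cut into consecutive 1020-bp
fragments; each is aligned locally (match 2, mismatch −3, open 5,
extend 2 — blastn-like) against the subject on both strands; fragments
with ≥ 30% identity and ≥ 70% coverage contribute their identity, and
ANI is their mean. The symmetric value averages the two directions;
species groups are single-linkage components above the threshold
(default > 96%). The upstream study delegated ANI to an external tool
without parameters; the ANIb convention is the field default.

## Ancestral trait reconstruction

F81 over an arbitrary discrete state set:
`P(i→j|t) = e^(−βt)δᵢⱼ + (1−e^(−βt))πⱼ`, `β = 1/(1−Σπᵢ²)`, branch
lengths in expected substitutions. Likelihoods by Felsenstein pruning
with per-node scaling; marginal posteriors by the up–down
(inside–outside) pass, `post(v) ∝ inside(v)·outside(v)`, root prior π.
Polytomies are allowed (pruning generalises); zero-length branches use
the t = 0 identity limit, so a zero-length discordant cherry has zero
likelihood and is reported as −∞ rather than an error. Equilibrium
frequencies are either empirical leaf proportions or maximised by
Nelder–Mead over softmax-parameterised simplex coordinates started from
the empirical proportions (a derivative-free search is robust to the
likelihood's flat ridges at this dimension; tolerance 10⁻⁸).
Never-observed states are floored at 10⁻⁶ and renormalised to keep the
likelihood finite.

MPPA selection: per node, among prefixes of the posterior-descending
state order, the subset S* minimising the Brier distance
`Σᵢ(pᵢ−eᵢ)²` with `eᵢ = 1/|S*|` inside the subset; ties go to the
smaller subset. Ambiguous nodes therefore keep multi-state sets — the
honest output when the data cannot decide an ancestor's morphology.

## Muropeptide quantification

UV absorbance at 204 nm scales with muropeptide subunit content, so a
peak's molar abundance is its area divided by its oligomer unit count
(1–4); molar percentages normalise these to 100. The default crosslink
statistic is the Glauner-style crosslinked-stem fraction
`Σ molar%·(n−1)/n` (an n-mer has n stems, n−1 crosslinked); the simpler
crosslinked-muropeptide fraction (total oligomer molar%) is also
emitted, and the per-unit normalisation can be disabled for peak tables
that are already molar. All outputs are invariant under rescaling of
the areas.

## The synthetic clade generator

The generator emulates the comparison design the analyses assume: a
clade of annotated genomes in two phenotype groups (defaults 5 MuLDi-like
vs 32 rod-like, mirroring the motivating comparison), with core families
present once per genome (default 30, mean protein length 120 — chosen
for desk-scale testability), families gained only in group A (7), lost
only from group A (4), and diagnostic residues planted at interior
positions (≥ 6 from either terminus) of 3 core families.

Sequences evolve by i.i.d. residue substitution along a random
ultrametric tree whose root-to-leaf height is half the target pairwise
divergence (per-branch substitution probability `1 − e^(−ℓ)`); no
indels by default. Because lineages share stem branches, substitutions
fixed on a group's stem produce *additional* genuine group-diagnostic
sites beyond the planted ones — as real evolution would — so
recovery tests assert that planted sites are found, not that they are
the only ones. Genomes are concatenated CDS (synonymous codons drawn
independently per genome, stop codons included, translation table 11)
with 20–50 bp random spacers, strands alternating to exercise
minus-strand handling. Independent codon choice means nucleotide-level
identity between genomes is substantially below protein-level
similarity, which keeps the ANI module's species grouping non-trivial.

Counts are NB2 per core family per genome with a planted group effect
(`mean_B = mean_A·2^lfc`, alternating sign) on the first `n_de`
families; α = 0 draws Poisson. Library-size variation is off by default
and available through `size_factor_sigma`.

Not emulated: realistic codon usage or GC skew, operon structure,
indels (optional hooks deliberately omitted rather than half-done), gene
order rearrangement, raw sequencing reads, and within-species
polymorphism. Passing recovery tests on these clades therefore
demonstrates the correctness of the decision rules and estimators under
the stated statistical model, not robustness to annotation errors or
alignment artefacts in real assemblies — for that, real search output
can be ingested via the tabular path.

## Problem sizes and determinism

The validation suite runs the full 5-vs-32 clade for gene-content and
site recovery, 2000-cluster null and 400-cluster power panels for the
expression contrast, 200 random ≤ 6-leaf trees against the enumeration
oracle, 100 random pairs against the alignment oracle, 1000 vectors
against the BH oracle, and 6-kb genomes for ANI — sizes at which each
check is statistically meaningful yet the whole suite runs in well under
a minute of compute per module. Every stochastic component takes an
explicit seed; a fixed configuration reproduces byte-identical fixture
files and pipeline checksums (manifest timestamps aside).
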