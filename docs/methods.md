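# Methods

This note documents the models and procedures `baiminer` implements,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical conventions used throughout.

## Scope and conventions

All coordinates are 0-based, half-open; strands are `+`/`−`; FASTQ
qualities are Phred+33. Every stochastic component is a pure function of
an explicit integer seed, and the pipeline derives all stage randomness
from the single seed in its configuration, so a fixed (config, seed)
pair reproduces byte-identical outputs.

## Discovery: ORFs and iterative homology search

ORFs are predicted in all six frames as methionine-initiated,
stop-terminated maximal stretches (bacterial code, translation table
11). The default minimum protein length is 100 residues — roughly half
the length of the 177-aa BaiE marker — so operon-scale genes are always
retained while short spurious frames are mostly suppressed.
Unterminated stretches at contig ends are not reported, which keeps the
interval invariant (protein length = interval/3 − 1) exact.

Pairwise protein search is optimal Smith–Waterman local alignment with
BLOSUM62 and BLAST-convention affine gaps (a gap of length *g* costs
11 + *g*). Bit scores use the standard gapped Karlin–Altschul
parameters for BLOSUM62 11/1 (λ = 0.267, K = 0.041); E-values use the
product of sequence lengths as the search space unless an explicit
database size is configured. Percent identity is computed over all
aligned columns with gap columns in the denominator; query coverage is
the fraction of query residues inside the local alignment. A hit passes
when identity and coverage both reach the stage thresholds: 50%/90% for
reference-database searches, 30%/90% for metagenome ORF searches.

Iterative expansion alternates search, similarity-network clustering,
and cluster-level acceptance (clusters must contain at least one
current query; a neighborhood-verdict callback can additionally veto
clusters), then promotes accepted members to queries. The accepted set
is monotone non-decreasing and bounded by the database, so a fixed
point always exists; the reported round count is the number of rounds
that accepted new members (minimum 1). A configurable cap (default 20
rounds) turns a logic error into a diagnostic rather than a hang.

## Similarity networks

Edges connect protein pairs whose alignment score −log₁₀E reaches the
threshold (default 70), with the score clamped at 300 to absorb
E-value underflow. The all-vs-all stage always uses pairwise
length-products as the E-value space so the graph is independent of
input order and batch composition. Clusters are connected components,
numbered by descending size with ties broken by the lexicographically
smallest member id; singletons are retained as clusters. The
within-cluster identity reported per cluster is the **minimum** pairwise
percent identity over members — the most conservative reading of a
"proteins within a cluster share ≥ x% identity" statement.

## Neighborhood completeness

ORFs within 15 kb on either side of the anchor (a *baiE* hit) are
assigned to the reference gene with the best alignment bit score,
admitted at ≥ 30% identity and ≥ 50% coverage **of the reference
protein** — looser than the discovery filter because neighborhood genes
diverge more than the marker. The window default reflects the ~12 kb
span of known *bai* operons. A contig is a *candidate* iff the seven
operon-local genes {baiA, baiB, baiCD, baiE, baiF, baiG, baiH} are all
present; the barA/barB regulators and the distally encoded baiN/baiK
are reported but never affect the verdict, and duplicated genes (the
two baiF paralogs) count once. A cluster is *candidate* if any member
contig is, *indeterminate* if no member has a neighborhood beyond the
anchor (short contigs), and *non-candidate* otherwise.

## Abundance

Reads are trimmed from both ends with a sliding window of 10% of the
current read length while the terminal window's mean quality is below
Q30; reads shorter than 50 bp are dropped. Recomputing the window from
the current length makes trimming idempotent. The CPM denominator is
the post-trim read count, matching the stated pipeline order (trim,
then map, then normalize).

Read assignment applies the best-match criteria — highest-scoring local
alignment at ≥ 90% identity over ≥ 20 aligned bases, each read counted
at most once, score ties to the lexicographically smallest cluster —
with two interchangeable engines. The default engine seeds candidate
reference/strand/diagonal triples with exact 16-mers sampled every 4
positions (guaranteed to find any error-free window of ≥ 19 bp, so at
the modeled error rates effectively lossless) and then computes the
optimal *gapless* local alignment on each seeded diagonal as a
maximum-sum segment. Under the substitution-only error model of the
read simulator this is exactly the optimal local alignment, at a small
fraction of the cost of full dynamic programming. The `exact` engine
runs full Smith–Waterman (match +1, mismatch −1, gap −2) against every
reference on both strands and is the cross-check reference; the test
suite asserts the two engines agree on mixed-community read sets.

## Association statistics

Group comparisons use the two-sided Mann–Whitney U: exact enumeration
when the combined sample is ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections. Stars follow the
conventional mapping (p < 0.05/0.01/0.001). No multiple-testing
correction is applied by default — results are reported raw — with
Benjamini–Hochberg available as a separate call. The bile-acid ratio is
(DCA + LCA)/(CA + CDCA); samples with a missing metabolome or a zero
primary pool are excluded pairwise, never imputed. Spearman correlation
uses midranks for ties and the t-approximation with n − 2 degrees of
freedom. The choice of the Mann–Whitney U as the two-group test is a
design decision: it is the standard nonparametric test for skewed CPM
distributions annotated with significance stars.

## Comparative genomics

ANI follows the orthologous-fragment algorithm: genomes are cut into
non-overlapping 1020 bp fragments; fragment pairs are aligned
(nucleotide local alignment, blastn-like scoring +2/−3, gaps 7/2, both
strands) and admitted at ≥ 35% identity and ≥ 35% coverage — the
published tool defaults; ANI is the mean identity over reciprocal
best-hit pairs, which makes it symmetric by construction. A 12-mer
prescreen skips fragment pairs sharing no exact 12-mer; at the identity
regimes where ANI is meaningful (≳ 80%) homologous fragments share many
12-mers, so the prescreen only removes non-homologous pairs. The
species boundary defaults to 95%, the midpoint of the conventional
94–96% band, and is configurable.

Neighbor joining is the classical Saitou–Nei algorithm with the
Q-criterion, deterministic tie-breaking (lowest index pair), and
negative limb lengths clamped to zero with the deficit moved to the
sibling limb (their sum, the joined distance, is preserved). The
implementation recovers additive matrices exactly (verified against an
independent path-summation oracle at 4–8 taxa and against a second NJ
implementation). Distances for marker-protein trees are p-distances
with pairwise gap deletion; pre-aligned concatenated sequences are
expected as input. Bootstrap support and maximum-likelihood inference
are out of scope.

## Mass arithmetic

Monoisotopic masses are sums of most-abundant-isotope masses from the
NIST table; adducts use the proton-mass convention (electron mass
neglected, documented): [M+H]⁺ = M + 1.007276. Thioester condensation
is formula addition minus H₂O; the BaiA oxidation is −H₂ and commutes
with condensation. Computed [M+H]⁺ values for cholyl-CoA and
3-oxo-cholyl-CoA sit ~3 ppm below the printed instrument values, within
the ~10 ppm window expected for observed-vs-theoretical comparisons on
a Q-TOF.

## Synthetic data: what it emulates, and what it does not

* **Protein families** are derived from a common ancestor by i.i.d.
  point substitution at rate 1 − target identity, with replacement
  residues drawn from BLOSUM62-conditional weights (∝ 2^(s/2)) so
  mutated pairs score realistically. Identity is parameterised *to the
  ancestor*; two members at ancestor-identity *t* sit near *t²*
  pairwise. The initiator methionine is exempt so members remain
  translatable ORF products.
* **Contigs** embed each gene as a real ORF via reverse translation
  with uniform synonymous codons (table 11; codon bias is irrelevant to
  the tested logic). Intergenic spacers are (CTAG)ₙ — a palindromic
  period-4 repeat with stop codons in all six frames and no ATG — so
  planted ORFs can neither start inside nor read through spacers, and
  planted intervals are always recovered exactly. Chance stop-free
  stretches in alternate frames of long genes can add extra ORFs; the
  neighborhood annotator reports them as "unassigned" and they never
  affect verdicts.
* **Reads** are drawn from contigs with probability ∝ abundance ×
  length, uniform positions, random strand, substitution-only errors
  (no indels: the mapping criterion is identity/length-based, so indels
  add noise without exercising new logic) and constant Q40 qualities.
* **Metadata** plants a Spearman correlation between abundance and the
  bile-acid ratio through a Gaussian copula on the normal scores of the
  abundance ranks with latent Pearson correlation 2·sin(πρ_s/6), which
  calibrates the realized Spearman ρ analytically (exact ±1 in the
  noiseless limits). Disease labels come from a logistic link on
  standardized log-abundance with slope equal to the group effect;
  at effect 0 the labels are exchangeable, which is what the
  type-I-error calibration checks.

The generators do **not** model fragment-size or GC bias, indels,
strain-level haplotypes, chimeric contigs, or real taxonomic
composition. Tests passing on these inputs demonstrate that the
*decision rules and statistics* behave as specified — thresholds
bracket correctly, planted structure is recovered, error rates are
calibrated — not that any biological conclusion from real cohorts is
reproduced. Reproducing cohort-level numbers would require the original
sequencing archives and is out of scope.

## Problem sizes

Default verification sizes were chosen so the full suite exercises every
claim at statistically meaningful scale while staying desk-sized: 3 × 8
proteins for partition recovery, 200 000 reads across six planted
clusters for abundance recovery (the binomial 3σ envelope at the
smallest planted fraction, 0.3%, is then ±0.012 percentage points),
2000 permutation replicates for test calibration (±1.5 points at 3σ
around the nominal 5%), 50 seeds × 140 samples for correlation
recovery, and a 12-sample community for the end-to-end fixture.

## Known limitations

* E-values are internally consistent but not calibrated to NCBI BLAST
  (no composition-based statistics, no length corrections); the network
  threshold of 70 should be interpreted within this scoring scheme.
* The seeded read-matching engine is exact only under substitution-only
  errors; for indel-rich data the `exact` engine (or an external
  mapper) is the right tool.
* Whether the CPM denominator should be raw or post-trim reads is
  ambiguous in the workflow this package operationalizes; post-trim is
  used, consistent with the stated stage order.
* The 92.4%-style within-cluster identity summary is implemented as the
  minimum pairwise identity; other summaries (mean, median) would be
  looser.
* ANI is undefined (raised, not defaulted) when no fragment pair passes
  admission, as between unrelated genomes.
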