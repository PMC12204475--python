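# Methods

This note documents the models, estimators and conventions behind
airrtoolkit, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Input dialects and normalisation

Seven upstream pipelines are supported through frozen *dialect signatures*:
for each pipeline, the required column set of its published output schema,
its delimiter, its row layout (one row per contig, one row per cell, or
chains packed into list columns), and which count field it guarantees.
Detection scores each signature by required columns present; a signature
matches only when its full required set is present, and the largest full
match wins. Ties raise an explicit ambiguity error and near-misses name the
closest candidates and their missing columns, so a misclassified file fails
loudly rather than silently. The normalised schema is one row per chain
contig: barcode, contig id, locus (TRA/TRB/TRG/TRD/IGH/IGK/IGL), V/D/J/C
calls, CDR3 amino-acid and nucleotide junctions, read and UMI counts, a
productive flag, and a sample id.

Count-field guarantees differ by pipeline and are recorded in the
signature: 10x, AIRR, BD and MiXCR provide both reads and UMIs; Parse and
WAT3R provide molecule/UMI counts only; TRUST4's barcode report provides
read counts only. Chain ranking therefore orders by UMIs first and falls
back to reads, so ordering is stable across dialects whenever the two are
concordant. Missing gene calls and junctions normalise to a single "NA"
sentinel; empty strings and None-like values map to it. Non-productive and
multi-locus ("Multi") rows are loaded as-is — filtering is the assembly
step's responsibility, keeping loaders lossless and row-order preserving.

The WAT3R layout is a one-row-per-cell TRA/TRB table; it cannot carry B-cell
chains or more than one contig per chain slot, and the emitter refuses such
data rather than dropping it silently.

## Paired clonotype assembly

Chains are assigned to two slots: chain 1 (TRA, TRG, IGK, IGL) and chain 2
(TRB, TRD, IGH). Within a slot, chains are ordered by UMIs (descending),
then reads (descending), then junction nucleotide string; the top two are
kept by default and joined with ";" (the upstream convention for reporting
a secondary chain), or only the top one when `filter_multi` is set.
Barcodes with both alpha-beta and gamma-delta TCR chains keep the locus
pair with more total UMIs (ties favour alpha-beta); the rule is arbitrary
but deterministic. Allele suffixes (`*01`) are stripped from gene calls at
consolidation so clone identity is stable across pipelines that do or do
not report alleles.

Clone identities per cell follow the `<chain1>_<chain2>` convention with
missing parts rendered "NA": `CTgene` joins V.J.C (chain 1) and V.D.J.C
(chain 2); `CTnt`/`CTaa` join the junction strings; `CTstrict` joins
`CTgene` and `CTnt`. Barcodes are prefixed `<sample>_<barcode>` to prevent
cross-sample collisions; the raw barcode is retained in its own column, so
the prefixing is reversible.

B-cell clonotype inference links heavy-chain (IGH) junctions that share
both V and J gene and reach normalized Levenshtein similarity ≥ 0.85 on the
nucleotide junction; connected components define inferred clones. The
nucleotide sequence (rather than amino acid) is the stricter choice and
matches somatic-hypermutation-aware practice. Light chains do not enter the
linkage rule; they only appear in the final `CTstrict` label (as light-chain
V.J), and cells without a heavy chain fall back to a light-chain-only
identity. Doublet detection flags barcodes with at least one productive
chain in each of the TCR and BCR locus sets.

## Clonal metrics

The substrate of all quantification is the clone-by-group count table.
Homeostasis bins are right-closed intervals on the per-group clone
proportion with defaults (0, 1e-4] Rare, (1e-4, 1e-3] Small, (1e-3, 0.01]
Medium, (0.01, 0.1] Large, (0.1, 1] Hyperexpanded — a configurable
convention, not a biological constant. Rank-based clonal space uses splits
(10, 100, 1000, 10000, 30000, 100000) on clones ordered by count with
lexicographic tie-breaks (determinism over aesthetics; all tie-breaks in the
package are lexicographic). Clone tracking selects the union over groups of
each group's top-n clones, so the selection is invariant to group order.
The abundance-weighted overlap is Morisita–Horn,
2·Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y), bounded [0, 1] and invariant to
proportional rescaling of either repertoire.

## Diversity and rarefaction

All entropies are in nats; normalized entropy divides by ln S. Chao1 uses
the bias-corrected form S + f₁(f₁−1)/(2(f₂+1)).

Two resampling schemes are deliberately distinct in the API:

* **Downsampling** (without replacement) equalises sequencing depth before
  comparing indices across groups: each of 100 replicates draws the
  smallest group's cell count from each group's cell-level clone labels and
  recomputes the indices. When the target equals the group size every
  replicate is a permutation, so the bootstrap mean reproduces the point
  estimate exactly — a useful self-check.
* **Multinomial bootstrap** (with replacement from the empirical clone
  frequencies) provides percentile confidence intervals for rarefaction
  curves (default 50 replicates, chosen for cost; percentile rather than
  normal-approximation intervals because curve estimates can be skewed near
  the asymptote).

Sample-size-based Hill-number estimation follows the standard
interpolation/extrapolation framework. Interpolation: q=0 uses the exact
hypergeometric expectation Ŝ(m) = S − Σᵢ C(n−xᵢ, m)/C(n, m); q=1
exponentiates the entropy of the expected subsample frequency counts
f̂ₖ(m) = Σᵢ C(xᵢ,k)C(n−xᵢ,m−k)/C(n,m); q=2 uses the closed form
1/(1/m + (1−1/m)·Σxᵢ(xᵢ−1)/(n(n−1))), valid at every m. Extrapolation:
q=0 approaches the Chao1 asymptote S + f̂₀(1 − (1 − f₁/(nf̂₀+f₁))^(m−n));
q=1 mixes the observed entropy with the singleton/doubleton-corrected
asymptotic entropy estimator in proportion n : (m−n), approaching the
asymptote as m grows; q=2's closed form extrapolates directly. Binomial
coefficients are computed in log space (gammaln), so depths of 10⁶ cells do
not overflow. At m = n all three orders reduce exactly to the observed Hill
numbers — this consistency is enforced to 1e-9 in the tests.

STARTRAC indices per transcriptomic cluster j: expansion
expa = 1 − H(clone sizes)/ln N over the N distinct clones in the cluster
(reported missing when N ≤ 1, where the ratio is undefined); migration and
transition are cell-count-weighted means, over clones present in the
cluster, of the entropy of each clone's cells across tissues respectively
across clusters. Weighted-per-cluster averaging is the documented choice;
both indices are zero iff every clone in the cluster is pure.

## Sequence composition

Positions are left-aligned: position 1 is the first junction residue, and a
position's support is the number of sequences long enough to reach it. (An
IMGT-gapped alignment mode is out of scope.) Positional entropy applies the
same Shannon machinery as the diversity module to the residue counts at one
position, with normalized entropy dividing by ln 20. Physicochemical
profiles use the five published Atchley factors (AF1 polarity, AF2
secondary structure, AF3 molecular size, AF4 codon composition, AF5
charge), embedded as constants and pinned by a checksum test; per-position
CIs are the normal approximation mean ± 1.96·sd/√n, missing where fewer
than two sequences cover the position. K-mer spectra normalise per window
pool (motif count over all counted windows in the group, not per sequence);
windows crossing a ";" chain separator or containing out-of-alphabet
characters are skipped. Multi-chain cells contribute their first
(highest-UMI) chain by default.

## Edit-distance clustering

Similarity is 1 − lev(a,b)/max(|a|,|b|) with unit costs, case-sensitive, on
amino-acid or nucleotide strings as the caller chooses; the default
threshold is 0.85. Two lossless prefilters bound the pair search: the
length filter (|len difference| > ⌊(1−t)·max⌋ cannot reach threshold t) and
a character-bag filter (edit distance ≥ max length − multiset intersection,
computed vectorised from per-sequence letter counts). Surviving pairs are
verified with a banded edit-distance computation that stops once the
threshold-implied bound ⌊(1−t)·max⌋ is exceeded. Identical sequences
collapse to one node with a multiplicity; components are labelled
`[<chain>.]cluster.<k>` by decreasing component size with lexicographic
tie-breaks. V-gene gating is off by default and available as a flag;
grouped clustering runs independently per group. On random sequence sets
the prefilters reject nearly all pairs, so measured work grows far more
slowly than the quadratic pair count; the test suite logs the measured
time ratio when doubling the input.

## Synthetic repertoires

The generator emulates a single 10x-scale sample: clone sizes from a
geometric law (p = 0.2, mean clone size 5; explicit sizes and a power law
are available), one V/J combination and one C...F-anchored CDR3 per clone
per chain, junction nucleotides back-translated codon-by-codon (uniform
over synonymous codons) so amino-acid and nucleotide clone calls agree by
construction, UMIs uniform in [5, 50) with reads = 10×UMIs, 1% planted
TCR/BCR doublets, 10% missing first chains, and 5% secondary first chains.
Gene catalogs are synthetic names (TRBV1..TRBVk), deliberately avoiding any
dependency on germline reference downloads. For BCR simulations a
controllable number of point substitutions is planted in each non-founder
cell's heavy junction, placing within-clone similarity above or below the
clustering threshold on demand.

What the generator does **not** emulate: V(D)J recombination statistics and
generation probabilities, somatic-hypermutation lineage structure, ambient
contamination, chimeric contigs, or sequencing error in the junctions.
Passing end-to-end tests therefore demonstrates that the pipeline's
bookkeeping (format round trips, pairing, counting, resampling) is exact
under clean conditions and that planted signals (doublets, sub-/supra-
threshold mutants) are recovered — not that biological clone calls on real
data are error-free.

## Numerical and scale choices

Exact-recovery tests and the acceptance script simulate 10,000 cells with
dropout and secondary-chain rates set to zero, since clone-size recovery is
only exact when every cell carries both chains; doublet planting stays at
1%. Oracle comparisons use 10,000-draw Monte-Carlo subsampling with a
3-standard-error band plus a 1/B floor (events rarer than one draw in B are
invisible to the oracle). Clustering oracle equivalence is checked on 500
sequences against brute-force all-pairs dynamic programming. All random
draws flow through seeded NumPy generators; fixed seeds give bit-identical
tables, and pipeline artifacts carry a provenance header with the tool
version, a hash of the semantically meaningful configuration, and the seed.

## Known limitations

* ACE and coverage-based rarefaction are not implemented (sample-size-based
  only); no asymptotic diversity profiles.
* Single-cell framework objects are not manipulated directly; the contract
  is a barcode-keyed table that merges into any framework's metadata.
* The 10x JSON contig format is not read (the CSV dialect is).
* No germline reconstruction, mutation trees, or isotype-switching
  analysis; no TCR-specific distance kernels (e.g. TCRdist).
* Plotting is out of scope; all outputs are tidy tables designed to feed
  standard heatmap/alluvial/network tooling.
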