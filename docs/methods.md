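# Methods

## Study design and data model

The unit of analysis is the patient-matched pair: a pre-treatment Baseline
biopsy and one or more disease-progression (DP) biopsies from the same
patient. Each DP sample forms one pair with its patient's unique Baseline,
so a cohort of 21 patients with 44 DP biopsies yields 44 pairs, some sharing
a baseline. All expression is in TPM; all genomic intervals are 0-based
half-open internally (GTF I/O converts at the boundary); protein residue
coordinates are 1-based inclusive.

## Differential isoform calling

Within a pair, an isoform is evaluated only if it reaches `tpm_min`
(default 10 TPM) in at least one of the two samples. The fold change is
FC = (TPM_DP + c) / (TPM_Baseline + c) with pseudocount c = 0.1 TPM
(configurable; c = 0 is supported, with FC = +∞ on a zero baseline treated
as an up call). A call is emitted when |1 − FC| > 0.2 on the raw FC scale —
deliberately asymmetric (FC < 0.8 or FC > 1.2), matching the filter as
stated rather than a log-symmetric variant. Recurrence ranks isoforms by
max(n_up, n_down) with deterministic tie-breaks (concordance, then id), and
the concordance filter retains isoforms with |n_up − n_down| strictly
greater than 6.

Isoform diversity is the normalized Shannon entropy of a gene's isoform
proportions, H = −Σ p_i log2 p_i / log2 m for m ≥ 2 isoforms with a Laplace
pseudocount on TPM; single-isoform genes are reported missing. Altered
vs non-altered gene groups are compared with a two-sided Wilcoxon rank-sum
test on per-gene mean entropy.

## Event classification and PSI

Events are defined purely from transcript exon structure by pairwise
comparison, with exact flank-coordinate matching:

- **SE** — cassette exon present with both flanks in one transcript, flanks
  adjacent and cassette absent in the other.
- **RI** — a single exon [a,d) versus adjacent exons [a,b), [c,d) with
  b < c; the intron-retaining form is the inclusion form.
- **A5SS / A3SS** — two exons sharing one boundary with the flanking exon
  across the shifted boundary identical. Naming is strand-aware: a
  right-boundary (donor-side) shift is A5SS on the + strand and A3SS on the
  − strand. The longer exon is the inclusion form.
- **MXE** — disjoint exons X and Y between identical flanks, each transcript
  carrying exactly one, no transcript in the gene carrying both; the
  upstream exon is the inclusion form.

Events are deduplicated by (mode, coordinates), and support sets are
recomputed over *all* transcripts of the gene; events with empty or
overlapping support sets are dropped. The classifier is verified against an
exhaustive coordinate-tuple enumerator on 1000 random gene models. Two
symmetries hold and are tested: flipping the strand alone swaps A5SS↔A3SS;
mirroring coordinates *and* flipping strand (a reverse-complement) leaves
every mode invariant.

PSI is abundance-based: Ψ = Σ TPM(inclusion isoforms) / Σ TPM(inclusion ∪
exclusion isoforms), missing when the denominator is zero. This is a
deliberate divergence from junction-count likelihood models (e.g. rMATS):
the pipeline's input is an abundance matrix, not read alignments. ΔΨ per
pair is tested with a one-sample t-test against zero (≥ 3 informative pairs
required; fewer ⇒ the event is reported *untested*, not p = 1), BH-corrected
across tested events, and called significant when |mean ΔΨ| > 0.1 and
q < 0.05.

## Switch detection

For each gene, per-pair log2FC vectors (length = number of pairs, with
pseudocount) are computed for every isoform. A candidate switch is an
isoform pair with Pearson r < 0, |r| ≥ 0.5 and p ≤ 0.05. Degenerate case:
when *both* vectors are exactly constant with opposite nonzero signs — the
zero-noise, full-penetrance limit of a perfect switch — the pair is treated
as r → −1, p = 0; a single constant vector makes the correlation undefined
and the pair is skipped with a logged reason.

A cohort-level switch call additionally requires:

1. both isoforms pass the concordance filter with opposite signs
   (up isoform n_up − n_down > 6; down isoform < −6);
2. paired t-tests on log2(TPM + c) are significant with opposite signs at
   q ≤ 0.05, where q is BH-corrected across *all* isoforms with at least
   one differential call (the family-wise correction is what separates
   genuine recurrent switches from anti-correlated noise pairs, which can
   pass a nominal 0.05 gate by chance);
3. at least one pair in which the up isoform has an up call and the down
   isoform has a down call in the same pair.

The reciprocal-recurrence statistic counts exactly those joint pairs;
"switch in X% of biopsies" is 100 × n_reciprocal / n_pairs with half-up
rounding to two decimals. One call (the candidate with the most reciprocal
pairs) is emitted per gene.

## Protein diff and domain impact

The principal isoform is taken from an APPRIS-style table when supplied,
else the longest CDS (ties: longest transcript, then lexicographic id).
Alternative isoforms are globally aligned to the principal protein
(BLOSUM62, gap open −11, extend −1); gap runs become deletion/insertion
segments and mismatch runs substitutions. A substitution run of ≥ 10
residues extending to the C-terminus flags a frameshift — an alignment
heuristic chosen because the annotation bundle carries protein sequences
directly rather than CDS phase. Domain impact intersects deletion segments
with each domain interval: lost (full overlap), truncated (partial), intact
(none); a frameshift forces every domain starting at or after the first
frameshifted residue to lost. The functional screen keeps protein-coding
retained isoforms whose diff loses or truncates at least one domain, then
attaches gene-set memberships and ranks by recurrence.

## Enrichment and RBP screen

Over-representation uses the hypergeometric upper tail P(X ≥ k) (scipy's
stable survival function) with BH correction; sets with zero hits are
excluded from the BH denominator. The universe defaults to all genes with
at least one expressed isoform. Domain-centric enrichment is the identical
statistic with domains as the sampling unit. The RBP screen takes every RBP
with ≥ 1 binding site intersecting the target gene span (half-open
intervals; strand matching optional; no proximity filter, since distal
sites are credited), correlates RBP expression with each target isoform
across samples (per-pair log2FC scope available), filters at |r| ≥ 0.3 and
p ≤ 0.05, and ranks by max |r| with name tie-breaks.

## The synthetic cohort generator

The generator emulates the matched-pair study design: 21 patients, one
Baseline each, 1–3 DP biopsies per patient totalling 44. Defaults: 400
genes, 10% switch genes, effect size 4×, penetrance 0.5, log-normal
abundance with ln-mean 3.5 and ln-sd 0.8 (≈ 33 TPM median — the scale of
robustly expressed isoforms), multiplicative log-normal noise σ = 0.25, RBP
coupling 0.8.

Each switch gene has an inclusion isoform and a skip isoform identical
except for one in-frame 129-nt cassette exon (43 aa), with a domain
interval straddling the encoded peptide so skipping truncates it. Decoy
genes carry 2–5 isoforms covering all five event modes, built over shared
per-codon residues so protein differences are contiguous blocks; a quarter
of decoys receive *anti-correlated isoform noise pairs* that exercise
false-positive control of switch detection, and ~20% of derived decoy
isoforms are non-coding to exercise the coding filter.

Manifestation model: each DP sample has a latent "switch activity"
a_s ~ N(0,1); every switch gene manifests in exactly round(penetrance × 44)
DP samples, chosen as the top-scoring under a_s plus gene-specific jitter.
This makes the per-gene manifestation count deterministic (so the no-noise
up-call count is exact), while manifesting samples overlap across genes via
a_s — the same factor that scales the driver RBP's expression, giving the
RBP screen a recoverable signal. In manifested samples the inclusion
isoform is multiplied by the effect size and the skip isoform divided by
it, before noise. Programmed switch-isoform pairs are floored at 15 TPM
baseline: an isoform below the 10-TPM detection filter cannot carry a
detectable switch, and the generator guarantees identifiability of its own
planted signal (the no-noise limit must be exactly recoverable).

What the generator does **not** emulate: read-level sampling noise,
isoform-assembly artifacts, batch effects, correlated gene-gene structure
beyond the single latent factor, sequence-level RBP motifs, and the long
abundance tail of real transcriptomes. Passing tests therefore demonstrate
correctness of the statistical machinery under the declared generative
model, not performance on raw RNA-seq-derived matrices.

## Numerical choices and degenerate inputs

- Zero-variance paired differences: t = ±∞ with p = 0 (nonzero mean) or
  t = 0, p = 1 (zero mean), never NaN.
- PSI with zero total TPM is missing, and missing values are
  pairwise-deleted from correlations (error below 3 complete pairs).
- Percentages are half-up rounded to 2 decimals; tie-breaks everywhere are
  deterministic (documented per function), and all randomness flows from a
  single integer seed, making whole-pipeline reruns byte-identical.
- Problem sizes in the test and acceptance runs (400-gene cohorts, 1000
  random gene models for the classifier oracle, 50 seeded replicates for
  RBP recovery) were chosen so the full validation completes in a few
  minutes on one CPU while keeping every estimate's Monte-Carlo error well
  below the margins being asserted.

## Known limitations

- Event-to-isoform mapping is containment-based on exact coordinates; fuzzy
  flank matching (tolerant of small annotation discrepancies) is out of
  scope.
- The ΔΨ test is a paired t-test on abundance-derived PSI, not a
  junction-count likelihood; p-values are not comparable to rMATS output.
- Frameshift detection is heuristic in the absence of CDS phase.
- The switch-detection gates assume ≥ ~10 pairs; very small cohorts will
  have low power through the concordance filter.
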