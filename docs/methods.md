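# Methods

## Model

The method assumes that, absent selection, (i) single-nucleotide
substitutions are equally likely, so the silent : missense : nonsense
proportions of mutations in a gene follow the codon-space proportions
134 : 392 : 23 obtained by exhaustively enumerating the 61 × 9 = 549
possible single-nucleotide codon changes of the standard genetic code;
and (ii) mutation positions are uniform over the CDS. Departures from
these nulls — positional clustering of missense/in-frame (OG) mutations
and excess truncating (TSG) mutations — are the driver signals.

Counts are enumerated per table row after collapsing exact duplicates
(same gene, sample, position, class). The codon-space counts are
recomputed from the code table (via Biopython's standard codon table) at
import, not hard-coded.

### Correction factors

Per gene, `f_OG = max(0, 1 − (N_sil/N_OG)/(134/392))` and
`f_TSG = max(0, 1 − (N_sil/N_TSG)/(134/23))`. Degenerate cases take the
limits of the formula: with zero OG (resp. TSG) mutations the factor is
1 if the gene also has no silent mutations (no evidence of elevated
background) and 0 otherwise (silent-only load means background
dominated). Genes present in the CDS-length table but absent from the
reference table keep `f = 1` and an empty hotspot set: missing reference
data is not evidence of a high background rate.

### Hotspots

A position is a hotspot when its raw OG count is ≥ 2 **and**
`P(X ≥ k·f_OG) ≤ α` for `X ~ Binom(n_OG·f_OG, 1/L)`, α = 0.05 by
default. Two deliberate choices:

* **Upper tail.** The test is implemented as P(X ≥ k): it is the only
  orientation under which more clustering gives a smaller p-value and it
  matches the verbal definition of "probability of observing this many
  mutations at one position by chance".
* **Minimum cluster size 2.** With small n, P(X ≥ 1) can dip below α,
  but a single mutation is not clustering; singletons are never called.

There is no multiple-testing correction across positions within a gene;
BH correction is applied only to the per-gene pOG/pTSG lists, keeping
the reference step a deliberately permissive hotspot catalogue. The test
is per-nucleotide, not per-codon, so adjacent nucleotides of one codon
can be separate hotspots.

### Detection statistics

For each cohort gene with ≥ 1 non-silent mutation and a model entry:
`pOG = P(X ≥ k_hOG·f_OG)`, `X ~ Binom(n_OG·f_OG, n_hotspots/L)`
(pOG = 1 when the gene has no reference hotspots or no hits), and
`pTSG = P(X ≥ n_TSG·f_TSG)`, `X ~ Binom(n_tot·f_TSG, 23/549)`. Cohort
mutations at reference hotspot positions count toward `k_hOG` even if
the cohort itself shows no recurrence there — this is the point of the
two-step design: hotspots impossible to see in a small cohort are
borrowed from the large reference. Each p-value list is BH-adjusted
across the tested genes (the BH family is the tested genes, not the
genome); `qDG = qOG × qTSG`; drivers have `qDG ≤ α`.

The 20/20 classification scores use raw observed proportions
(`OG score = 100·k_hOG/n_OG`, `TSG score = 100·n_TSG/n_tot`, zero for
empty denominators): the ratiometric rule descends from Vogelstein's
observed-proportion heuristic, and correction factors cancel in the OG
ratio anyway. A `corrected_scores` switch applies the factors instead.
TSG ≥ 20 overrides OG ≥ 20 because a specific missense change can
inactivate a TSG while truncation rarely activates a gene.

### Numerical choices

* Corrected counts are real-valued; the binomial upper tail is evaluated
  as the regularized incomplete beta `I_p(k, n−k+1)` rather than by
  rounding, avoiding threshold artefacts. At integer counts this equals
  the exact binomial sum (tested to 1e-12 relative error against direct
  summation).
* `k = 0` returns tail probability 1 by convention.
* Output rows are sorted by ascending `qDG` with the gene symbol as a
  deterministic tie-break; identical inputs give byte-identical output.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| hotspot α | 0.05 | per-position significance in the reference step |
| driver α | 0.05 | threshold on qDG |
| score threshold | 20 (percent) | OG/TSG classification cut-off |
| min cluster size | 2 mutations | raw recurrence required for a hotspot |
| CDS lengths | — | nucleotides; canonical transcript = longest CDS on duplicates |

## Input handling

MAF `Variant_Classification` values map to OG (missense, in-frame
indels), TSG (nonsense, frameshift indels) or SILENT; everything else —
splice site, nonstop, translation start, UTRs, introns, RNA, unknown
strings — is EXCLUDED and tallied in the load report, since the model
defines no expectation for those classes. CDS positions are 1-based
nucleotides parsed from HGVS-style `c.` strings; an indel is anchored at
its first affected nucleotide (position only matters for OG clustering,
where in-frame indels are rare). Positions beyond the annotated CDS
length are kept for count statistics but excluded from positional
tallies, guarding against annotation-version mismatches.

## Synthetic data

The simulator emulates the study conditions the method targets:
100-sample cohorts over genes with per-gene per-nucleotide background
rates drawn log-normally (median ≈ 5×10⁻³ expected mutations per
nucleotide across the cohort, σ = 1 on the log scale), CDS lengths
uniform in 450–6000 nt. Neutral genes draw silent/missense/nonsense
counts at the codon-space proportions, so their correction factors
concentrate near zero — the method's own null. Planted oncogene-like
genes put 50% of their missense mutations on 3 fixed hotspot positions
with a 5% silent share; planted TSG-like genes make 50% of their
mutations truncating (nonsense/frameshift split evenly). Planted genes
carry an expected ≥ 40 mutations so the reference step can see their
pattern. Reference and cohort are independent draws from the same gene
plan (same lengths, rates, hotspot positions) under independent
substreams of one seed.

What the generator does **not** model: trinucleotide-context mutation
signatures, codon-usage bias, sample-level mutation-burden
heterogeneity, copy-number events, subclonal structure, and indels in
neutral genes. Passing the recovery and calibration tests therefore
shows the statistics behave as designed under their own assumptions; it
does not certify performance on real tumour cohorts, where context
effects can inflate apparent clustering.

Test and acceptance runs use 200 neutral + 5 + 5 planted genes — large
enough for a meaningful BH family and null-rate estimate while keeping
the whole suite in seconds.

## Known limitations

* Hotspots are 1-nt resolution with no 3-D or domain awareness;
  structure-aware clustering methods can find spatially coherent
  clusters this test misses.
* The equal-probability substitution model ignores mutational
  signatures; genes in signature-prone contexts can have mildly
  miscalibrated correction factors.
* The truncating-mutation null (23/549) is derived from nonsense events
  only; frameshift opportunity is not part of the codon-space
  denominator, making the pTSG test conservative-leaning on
  frameshift-rich data only insofar as the nonsense rate understates
  total truncation probability.
* Splice-site variants, which are often inactivating, are excluded
  rather than counted as truncating, because the model defines no
  expected rate for them.
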