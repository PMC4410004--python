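# somdriver

Detection of candidate cancer driver genes from somatic mutation
cohorts, and their classification into oncogenes (OG) and tumour
suppressor genes (TSG).

## The problem

Most somatic mutations in a tumour are passengers; only a handful of
driver mutations, concentrated in driver genes, confer a selective
growth advantage. Two mutation patterns betray positive selection across
a cohort of tumour samples:

* **oncogenes** accumulate missense mutations that *cluster* at
  recurrent CDS positions (hotspots), because only specific amino-acid
  changes activate the protein;
* **tumour suppressor genes** accumulate *protein-truncating* mutations
  (nonsense and frameshift) spread along the whole gene, because almost
  any truncation inactivates it.

`somdriver` turns both patterns into per-gene statistics, corrected for
each gene's background mutation rate, so that frequently mutated
background genes (the TTN-like "artefacts" of naive frequency filters)
are deprioritized while rarely mutated true drivers remain detectable.

## The method

**Step 1 — reference.** From a large reference mutation table (e.g. a
COSMIC-like export), for each gene:

* Two correction factors from the silent-mutation load. Exhaustive
  enumeration of the standard genetic code (61 non-stop codons × 9
  substitutions = 549 possible mutations: 392 missense, 23 nonsense,
  134 silent) gives neutral silent-to-missense and silent-to-nonsense
  ratios of 134/392 and 134/23. The factors are

  ```
  f_OG  = 1 − (N_sil/N_OG)  / (134/392)      (clamped to [0, 1])
  f_TSG = 1 − (N_sil/N_TSG) / (134/23)
  ```

  where OG mutations = missense + in-frame indels and TSG mutations =
  nonsense + frameshift indels. A gene mutated mostly by background has
  a proportionally high silent load and a factor near 0.

* **Hotspots**: any CDS nucleotide position carrying k ≥ 2 OG mutations
  whose upper-tail binomial probability
  P(X ≥ k·f_OG), X ~ Binom(n_OG·f_OG, 1/CDS length), is ≤ 0.05.

**Step 2 — detection.** Each cohort gene (from a MAF file) is scored
against the reference:

* `pOG` = P(X ≥ k_hOG), X ~ Binom(n_OG, p_h) with p_h = hotspots/CDS
  length, counts weighted by f_OG — the probability that so many of the
  gene's OG mutations land on known hotspots by chance;
* `pTSG` = P(X ≥ k_TSG), X ~ Binom(n_tot, 23/549), counts weighted by
  f_TSG — the probability of so many truncating mutations under the
  neutral nonsense rate.

Both lists are Benjamini–Hochberg adjusted across tested genes and
combined into the driver statistic **qDG = qOG × qTSG**; a gene is a
putative driver when qDG ≤ 0.05. Drivers are classified with a
20/20-style rule on observed proportions: TSG if ≥ 20% of mutations are
truncating (truncation overrides clustering), else OG if ≥ 20% of OG
mutations sit on hotspots, else unclassified.

Fractional (corrected) counts are handled by evaluating the binomial
tail through the regularized incomplete beta function,
P(X ≥ k) = I_p(k, n − k + 1), which reduces to the exact binomial sum at
integer counts.

## Worked example

No downloads are needed: the built-in simulator generates a reference
table and a cohort MAF with known ground truth (200 neutral genes plus 5
planted oncogene-like and 5 planted TSG-like genes by default):

```sh
somdriver simulate --seed 1 --out demo
somdriver build-ref --mutations demo/reference.tsv \
                    --cds-lengths demo/cds_lengths.tsv --out demo/model
somdriver detect --maf demo/cohort.maf --ref demo/model --out demo/results.tsv
```

The `build-ref` log reports `reference model: 210 genes, 18 hotspots`
and `detect` reports `204 tested genes, 10 putative drivers`. The top of
`demo/results.tsv`:

| gene  | n_og | n_tsg | k_hog | q_dg     | og_score | tsg_score | call |
|-------|------|-------|-------|----------|----------|-----------|------|
| OG01  | 48   | 1     | 27    | 1.3e-57  | 56.2     | 2.0       | OG   |
| OG03  | 36   | 3     | 19    | 4.6e-46  | 52.8     | 7.7       | OG   |
| OG02  | 35   | 1     | 13    | 3.0e-29  | 37.1     | 2.8       | OG   |
| TSG02 | 20   | 25    | 0     | 1.0e-20  | 0.0      | 55.6      | TSG  |
| TSG03 | 14   | 23    | 0     | 1.1e-20  | 0.0      | 62.2      | TSG  |

All ten planted genes are recovered with qDG ≪ 0.05 and the correct
OG/TSG call; every neutral gene is reported `NOT_SIGNIFICANT`. `k_hog`
is the number of the gene's OG mutations found at reference hotspots,
and the scores are the 20/20-rule percentages (OG01: 56% of its missense
mutations on hotspots; TSG02: 56% of its mutations truncating).

With `--benchmark genes.txt --top-k 10,30,100`, `detect` also prints the
fraction of the top-ranked genes present in a benchmark list (e.g. the
Cancer Gene Census), the standard enrichment read-out for driver-gene
rankings.

Real data plug in the same way: convert a COSMIC mutant export with
`python scripts/convert_cosmic.py export.tsv reference.tsv`, then point
`build-ref` at it and `detect` at any standard MAF.

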