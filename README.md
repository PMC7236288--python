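# mitorepeats

Exhaustive identification, quantification and comparison of **direct and
inverted repeat sequences** in mitochondrial genomes.

Mitogenomes — compact circular molecules of roughly 16–18 Kbp in
vertebrates — are usually described as structurally stable, yet they carry
large numbers of short repeats, and repeats are the raw material of
slipped-strand mispairing, deletions, duplications and inversions (the
tandem duplication–random loss model of mtDNA rearrangement). This package
is for researchers who want a complete, assumption-light census of that
repeat content across a cohort of genomes: every exact repeat, every
length, overlaps included, compared against a randomized control and mapped
onto the gene annotation.

## What it computes

For each genome and each repeat length k = 5…30 bp (100% identity):

* **Direct repeats (DRs)** — every forward-strand position whose k-mer
  occurs at ≥ 2 positions. The scan advances one nucleotide at a time, so
  overlapping occurrences count as independent findings.
* **Inverted repeats (IRs)** — every forward-strand position whose k-mer's
  reverse complement occurs on the forward strand (i.e. the word recurs on
  the complementary strand in inverted orientation).
* **Abundance** — repeats/Kbp = count ÷ (genome length / 1000), the unit in
  which genomes of different sizes are compared.
* **Randomization null** — each genome shuffled 10 times (uniform character
  permutation: identical length, identical base counts, identical GC),
  scanned the same way, giving per-(k, type) null distributions.
* **Cohort statistics** — ECDFs of abundance per (k, type); Brown–Forsythe
  (Levene) variance test; Welch's heteroscedastic one-way ANOVA
  F = Σwᵢ(x̄ᵢ−x̄w)²/(g−1) ÷ [1+2(g−2)/(g²−1)·A] with Welch–Satterthwaite
  denominator df, plus a conservative p value recomputed at **half the
  denominator df** to discount phylogenetic non-independence of species;
  per-order summaries with atypical-genome flags (> mean + 2 SD).
* **Genic/non-genic mapping** — occurrences classified against a genic mask
  built from GenBank features (gene/CDS/tRNA/rRNA genic; D-loop and spacers
  non-genic); bias reported as enrichment = genic share ÷ genic length
  fraction with a binomial test; BED-like map tracks and iTOL-style bar
  annotations exported.

Counting conventions (`occurrence` positions, `distinct` words, copy
`pairs`) are selectable throughout; see `docs/methods.md` for the model,
the palindrome and circularity rules, and the verification strategy (an
independent quadratic oracle must agree exactly with the scanner).

## Worked example

```python
from mitorepeats.fixtures import synthetic_mitogenome
from mitorepeats import scan_all, build_null

g = synthetic_mitogenome("demo", seed=42, length=17000)   # 17 Kbp, GC 0.40
prof = scan_all(g, 5, 30)
for k in (5, 9, 15, 30):
    print(k, prof.count(k, "direct"), round(prof.abundance(k, "direct"), 1),
          prof.count(k, "inverted"), round(prof.abundance(k, "inverted"), 1))

ens = build_null(g, n_replicates=10, seed=7)
print("longest repeat in shuffled replicates:",
      ens.max_k_with_repeats("direct"), "bp direct,",
      ens.max_k_with_repeats("inverted"), "bp inverted")
```

prints

```
5 16969 998.2 16395 964.4
9 2595 152.6 784 46.1
15 147 8.6 0 0.0
30 132 7.8 0 0.0
longest repeat in shuffled replicates: 16 bp direct, 16 bp inverted
```

Reading it: at 5 bp essentially every window is a repeat (998 DRs/Kbp); by
9 bp direct repeats (152.6/Kbp) are about three times as abundant as
inverted ones (46.1/Kbp); by 15 bp inverted repeats have vanished while the
control-region tandem array keeps producing direct repeats all the way to
30 bp (7.8/Kbp). The shuffled controls lose all repeats beyond 16 bp —
long repeats are a signature of sequence structure, not of composition.

## Command line

```bash
mitorepeats scan genomes.fasta --outdir out            # catalogs + profiles
mitorepeats null genomes.fasta --replicates 10 --seed 1
mitorepeats map genome.gb --k 9 --repeat-type direct   # genic/non-genic bias
mitorepeats fixture --length 2000 --plant 15:direct:2 --out fix.fa
mitorepeats run genomes.fasta --metadata meta.tsv --outdir out   # everything
```

`run` writes one catalog TSV per (genome, k, type), profile and null JSONs,
the cohort table, comparison reports, ECDF coordinates, map tracks and a
manifest with checksums; reruns with the same config and seed are
byte-identical.

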