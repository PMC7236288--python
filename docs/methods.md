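# Methods

## The repeat model

`mitorepeats` enumerates **exact-match repeats** in a DNA sequence for every
length k from 5 to 30 bp. Two repeat types are distinguished:

* **Direct repeats (DRs)** — a k-mer occurring at two or more positions on
  the same strand, same orientation.
* **Inverted repeats (IRs)** — a k-mer whose reverse complement also occurs
  on the forward strand; equivalently, the same word read on the
  complementary strand in inverted orientation.

The scan slides a window one nucleotide at a time, so **overlapping
occurrences count as independent findings**: `AAAAAA` contains two
occurrences of the 5-mer `AAAAA`. Overlaps are kept deliberately — partially
overlapping words are exactly the substrate of slipped-strand mispairing
during mtDNA replication, and counting them also gives the method residual
sensitivity to degenerate repeats despite the 100%-identity criterion.

Counts are normalised to **repeats per Kbp** (count divided by genome length
in kilobase pairs) so genomes of different sizes are comparable.

### Counting conventions

"Number of repeats" is ambiguous, so three conventions are implemented and
selectable everywhere (`occurrence` is the default):

| convention   | counts                                                        |
|--------------|---------------------------------------------------------------|
| `occurrence` | every position whose k-mer is repeated / has an inverted match |
| `distinct`   | distinct repeated k-mer strings                                |
| `pairs`      | matching window pairs: Σ C(m, 2) over repeated k-mers          |

For inverted repeats the `pairs` convention counts
Σ<sub>w&lt;rc(w)</sub> m<sub>w</sub>·m<sub>rc(w)</sub> over complementary
word couples, plus C(m, 2) same-word pairs for palindromic words (plus the m
self-matches when those are included, see below). The convention knob exists
because external repeat lists rarely document which quantity they report;
scanning the same genome under all three conventions lets a user calibrate
against such output empirically.

### Palindromes and circularity

A palindromic k-mer (w = rc(w), e.g. `GAATTC`) matches its own locus when
the complementary strand is read back. The default **includes** these
self-matches, which is what a literal "search the forward words in the
reverse-complemented genome" procedure finds; `include_self_palindrome=False`
drops palindromic words whose only inverted match is their own mirrored
locus. Mitogenomes are circular molecules; the default scan is nevertheless
linear (matching a naive string scan of the deposited sequence), and
`circular=True` adds the k−1 origin-spanning windows. Windows containing any
non-ACGT IUPAC code are excluded from indexing and matching — exact-match
semantics are undefined for ambiguity codes — and logged.

Under the occurrence convention (self-palindromes included) the per-genome
count is provably non-increasing in k: every length-(k+1) match contains a
length-k match at the same start position. This monotonicity is enforced as
a property test.

### Verification strategy

Correctness rests on a dual route. The production scanner uses a hash index
of k-mer start positions. An independent **quadratic oracle**
(`mitorepeats.oracle.brute_force_repeats`) compares every window against
every window (direct) or against every window of the reverse-complemented
sequence (inverted) via numpy pairwise equality matrices, sharing no code
with the scanner, and is capped at 4 Kbp. Tests require exact agreement
(positions, counts, all conventions) on hundreds of randomized sequences,
and the planted-repeat fixture generator refuses to emit a fixture until the
oracle confirms its ground truth is the sequence's complete repeat content
at the planted lengths.

## The randomization null

Each genome is compared against sequences with the same length and exact
base counts (hence identical GC content): **uniform random permutations of
its characters**, 10 replicates per genome by default. Permutation (rather
than i.i.d. resampling with matched frequencies) was chosen because only the
permutation preserves composition exactly; a test nevertheless checks that
shuffled replicates are statistically indistinguishable from i.i.d.
composition-matched sequences in mean 5-mer repeat abundance. Replicate r
of a run with master seed s draws from
`default_rng(SeedSequence(entropy=s, spawn_key=(r,)))` — a deterministic,
order-independent rule, so ensembles are reproducible byte for byte.
Mononucleotide shuffling destroys dinucleotide structure; users probing that
sensitivity should treat the null as a lower bound on sequence structure.

For k large enough that the expected number of collisions in a shuffled
sequence falls below ~1 (around 14–16 bp at mitogenome scale, depending on
composition), replicates show no repeats at all, while biological control
regions keep producing long repeats — the qualitative signature the null is
designed to expose.

## Cohort statistics

Per-genome abundances are stacked into a cohort table, one row per
(genome, source) with source ∈ {biological, random}; the random source
contributes each genome's **mean abundance over its 10 replicates** (one
point per organism, matching how control distributions are usually
plotted). Distributions are summarised as ECDFs, F(x) = proportion of
sample values ≤ x.

Group comparisons run the **Brown–Forsythe variance test** (Levene with
median centring, robust to the right-skew of large-k abundance
distributions) and, because variances are typically heterogeneous,
**Welch's one-way ANOVA** with Welch–Satterthwaite denominator df. The Welch
statistic is computed in-package (the df internals are needed below) and is
cross-checked in tests against `pingouin.welch_anova` and against the Welch
t² identity for two groups. With equal variances and sizes the Welch F
equals the classic ANOVA F exactly for two groups; for more groups the
correction term makes the reduction asymptotic only.

**Halved-df adjustment.** Species are not independent data points (shared
phylogeny), so every test result also carries a p value recomputed from the
same statistic with the **denominator df halved** (floored at 1) — the
denominator because that is the sample-size-driven df inflated by
non-independence; halving the numerator df too is available as an option.
For F ≥ 1 this adjustment can only increase the p value (the F tail fattens
as denominator df shrinks); for F < 1 the two p values are both near 1 and
the ordering can marginally reverse — irrelevant to any significance call,
but worth knowing. This heuristic is implemented as published practice; it
is not a substitute for formal phylogenetic comparative methods (PGLS,
independent contrasts), which are out of scope.

Genomes whose abundance exceeds the cohort mean by more than 2 cohort SDs at
a given (k, type) are flagged **atypical** (the multiplier is configurable).

## Genic / non-genic mapping

GenBank features of types {gene, CDS, tRNA, rRNA} (configurable) are
unioned into a per-position genic mask; the D-loop/control region and
intergenic spacers are non-genic. Whether rRNA/tRNA genes belong in "genic"
is a judgement call; they are included by default because they are
transcribed, functional loci. Feature strand is ignored — a position inside
any gene is genic regardless of strand, since repeat occurrences are
recorded on the forward strand only.

Each occurrence is labelled by **majority of its k bases** (ties for even k
resolved by the start base; a start-base-only rule is available). The bias
statistic is the enrichment ratio

    enrichment = (genic occurrences / total occurrences) / genic length fraction

with a two-sided binomial test of the genic count against the genic length
fraction. Enrichment 1 means no bias; < 1 means non-genic preference (the
direct-repeat pattern in repeat-rich genomes, concentrated in the control
region); > 1 means genic preference (the inverted-repeat pattern).

Map exports are BED-like TSV tracks in 1-based inclusive coordinates
(internal coordinates are 0-based half-open; the conversions are round-trip
tested), plus iTOL-style simple-bar annotation files for displaying
per-species abundances on a taxonomy tree.

## Synthetic data

Two generators supply all test and demonstration inputs; no real genome
files ship with the package.

`generate_fixture` plants direct copies (identical words) or inverted
couples (word + reverse complement) at known, non-overlapping coordinates in
an i.i.d. background, then **rejection-resamples the background until the
brute-force oracle confirms** that the planted occurrences — including every
sub-window of a planted copy at shorter checked lengths — are the sequence's
entire repeat content at the checked ks. The emitted truth catalog is exact,
which is what makes precision/recall-1 recovery tests meaningful. Planted
lengths of ~12 bp and up are practical; at shorter k the background of even
a 1–2 Kbp sequence is saturated with chance repeats and rejection cannot
succeed.

`synthetic_mitogenome` emulates the study material at realistic scale:
~16.5–17.6 Kbp circular sequences with an AT-rich, strand-skewed base
composition (A 0.34, C 0.29, G 0.11, T 0.26; GC 0.40 — the skew makes
reverse-complement matches rarer than same-strand matches, as in real
vertebrate mtDNA), a 1.2 Kbp control-region segment carrying a tandem array
of a 20–40 bp motif (the repeat-rich D-loop structure), and optional extra
dispersed direct 12-mers or inverted 12-mer couples to model repeat-rich
outlier genomes. `synthetic_feature_table` tiles the body with back-to-back
gene/tRNA features (~92% genic) and leaves the control region unannotated
except for a D-loop feature. What these fixtures do **not** emulate: codon
structure, dinucleotide bias, real gene order, heteroplasmy, sequencing
error. Passing tests therefore demonstrate the correctness of the
machinery, not any biological claim about real mitogenomes; cohort-level
numbers from the literature require the original genome set and knowledge
of the original counting convention, and are deliberately not asserted.

## Problem sizes and numerical choices

The test suite verifies oracle equivalence on 200 random sequences of
200–2000 bp (k 5–15, all conventions) and planted-repeat recovery on 50
fixtures of 1–2 Kbp; the acceptance script analyses a cohort of 9 synthetic
mitogenomes (3 per order) at full length and k range with 10 shuffle
replicates each — sizes chosen so a complete run stays in the minutes range
on one core while exercising every code path at realistic scale. Other
numerical choices: Welch's test refuses zero-variance groups (its weights
are n/s²); Levene centring is the median; the ECDF is right-continuous with
F(max) = 1 exactly; catalogs are sorted by position with deterministic
output ordering, and identical inputs yield byte-identical files.
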