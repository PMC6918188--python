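# Methods

This note documents the models, statistics, numerical choices and known
limitations behind `cresig`.

## Regulation calls and background rates

The meta-matrix holds one M-value (log2 expression ratio) per gene per array;
missing cells are allowed and excluded from every denominator.  Each array's
genes are partitioned into *induced* (M ≥ log2 f), *suppressed*
(M ≤ −log2 f) and *neutral*, with fold cutoff f = 2 by default and per-array
overrides (typically 1.5 for low-dynamic-range arrays; which arrays get the
override is the user's call, via a two-column TSV).  The boundary is
inclusive: "two-fold induced" is read as ≥.  Genome-wide proportions of the
three states over an array's non-missing calls are the null expectation for
all enrichment tests — the background population is *measured* genes, not all
annotated genes, since only measured genes can be called.

## The regulatory fingerprint

For a CRE's carrier set (genes with ≥1 occurrence of the pattern in the
chosen region), each array contributes three tests, mirroring the
induced-only / suppressed-only / all-differentially-expressed convention:

* a 1-df goodness-of-fit chi-squared of the binary split *target state vs
  rest* against the background proportion (no Yates continuity correction;
  expected cells < 5 are flagged `low_expected` rather than switched to an
  exact test);
* the combined test treats (induced + suppressed) vs neutral as the binary
  split by default; a 2-df three-category variant is available via
  `combined_3cat=True`.

Chi-squared is sign-blind, so each result carries a direction
(enriched/depleted) and the reporting convention — `is_enriched` — requires
*significantly more* genes in the target state.  Raw p-values at α = 0.05 are
the default (per-array decisions, no multiplicity correction); Benjamini–
Hochberg across arrays is available (`correction="bh"`, via
`scipy.stats.false_discovery_control`).  Degenerate arrays (no non-missing
call in the set) become flagged cells, not failures.

Stratified fingerprints re-run the same machinery on position bins (200-bp
upstream-distance bins; the distance of an occurrence is the 1-based distance
from the TSS to its nearest base, identical for both orientations), on
orientation strata (non-palindromic patterns only; a gene with hits in both
orientations joins both strata), and on copy-number strata (1, 2, 3, pooled
≥4).  Every stratum is tested against the same genome background; strata
below `min_stratum_n` (default 20) are reported with an `underpowered` flag.

## Pattern scanning

Patterns are IUPAC degenerate strings, 4–25 nt.  Matching is exact set
membership per position; an `N` in the *sequence* never matches (conservative,
since an unknown base is not evidence of a site).  All occurrences are
reported, overlapping ones included — this matters for copy number and is the
behaviour of exhaustive pattern matchers.  Both strands are scanned by
scanning the reverse-complemented pattern on the forward sequence; palindromic
patterns (fixed points of degenerate reverse complement) are scanned forward
only so their sites are not double counted, and their occurrences are all
recorded as forward — orientation analysis is restricted to non-palindromic
patterns.

## Region extraction

Regions are extracted strand-aware from FASTA + GFF3 and always written 5′→3′
in reading orientation.  Internal coordinates are 0-based half-open; all I/O
honours GFF3's 1-based inclusive convention.  Per gene, the longest-span mRNA
is used (one region per gene; genes are treated atomically).  The five kinds:
1-kb and 3-kb upstream of the TSS, 5′-UTR, introns (concatenated with a run of
30 N's — longer than the 25-nt maximum pattern width, so no pattern bridges
two introns), and 1 kb downstream starting at the base *after* the stop codon.
Flanks truncate at contig edges (empty at the edge itself, with a warning);
neighbouring genes are *not* masked out of flanks.

## Motif discovery

The forward search is a ZOOPS (zero-or-one occurrence per sequence) Gibbs
sampler:

* **Background**: order-k Markov (k ∈ 0..3, default 1), maximum-likelihood
  conditional frequencies with +1 pseudocount per cell, trained per region
  kind; training requires ≥ 100·4^k bp.
* **Site model**: width-w position frequency grid (w ∈ 8..25, default 8) with
  pseudocounts proportional to background marginals (total weight 1); site
  prior 0.5 per sequence; both strands sampled.
* **Sampling**: per sweep each sequence's site is resampled from
  P(site at i) ∝ (prior/n_options)·LR(i), P(no site) ∝ 1 − prior, where LR is
  the grid-vs-background likelihood ratio of the window.  Every 5 sweeps a
  greedy phase-shift move tries displacing the whole register by ±1 — without
  it the chain can lock one base off the true motif.  Default budget: 200
  sweeps × 10 restarts; the best-scoring configuration (joint log-likelihood
  ratio of the site set under its own grid) wins.  Everything is deterministic
  given the seed.
* **Ranking**: after a motif is reported its sites are masked to N and the
  search repeats, so successive motifs describe distinct signals.
* **Consensus**: per column, the smallest IUPAC code covering all bases with
  frequency ≥ 0.25 (falling back to the argmax base) — this yields degenerate
  8-mers comparable to curated CRE catalogs.

Co-existing-motif search restricts the sequences to an anchor CRE's carriers,
masks anchor occurrences (both strands; a flag disables masking, since
unmasked co-occurrence structure can itself be of interest), and *keeps the
background trained on all sequences of the region kind* — shared composition
must not masquerade as a co-motif.

Window scoring is implemented with packed 4-mer chunk codes (a window score is
a handful of 256-entry table lookups), which keeps a 100-sequence × 1-kb
search with the default budget near ten seconds on one CPU.

## TF association

Z = (X − µ)√n/δ per array, with µ and δ over all measured genes (δ is the
population standard deviation; configurable to sample sd) and X, n over the
set's non-missing genes.  Z is defined for any n ≥ 1 and missing only when the
set has no called gene on the array or the array has zero variance; the
all-gene set gives Z ≡ 0.  TF association is the Pearson correlation of the Z
profile with the TF's M-value profile over pairwise-complete arrays, requiring
coverage of at least ⌈0.8·A⌉ arrays (the "more than 80% of data sets" rule
generalised to any array count); below-coverage TFs are reported but excluded
from ranking.  T = r·√[(n−2)/(1−r²)] with a two-sided p from t(n−2);
numerically perfect correlations (|r| within 1e-12 of 1) get an infinite-T
sentinel and the minimum representable p.  "Fold-change values" of a TF are
its M-values in the same meta-matrix — no separate fold-change scale exists.
Strength bands are symmetric: strong |r| ≥ 0.5, moderate 0.3 < |r| < 0.5,
weak |r| ≤ 0.3.  The exported edge list keeps |r| ≥ 0.45 (inclusive), sorted
by |r| then p.

## Synthetic data: what it emulates, what it does not

The generator builds a single contig of gene blocks (1.2-kb promoter, 150-nt
5′-UTR inside a 300-nt first exon, 200-nt intron, 250-nt second exon, 1.1-kb
downstream, 100-nt spacer), genes alternating strands, background an order-1
Markov chain at GC 0.43 (rice-like) with a mild homopolymer bias.  Motif
planting controls carrier fraction, copy-number distribution, position bins,
and orientation policy; degenerate patterns are instantiated uniformly per
site; sites never overlap each other.  By default chance occurrences of the
planted pattern in the same region kind are resampled away (*exclusive*
planting) so the truth table is exact; `exclusive=False` leaves the background
untouched for chance-rate studies.

Expression is simulated per effect: a responder fraction of the carrier set
gets M ~ Normal(±Δ, noise sd) in the designated arrays; every other cell is
Normal(0, baseline sd); missingness is injectable at a stated rate.  TF rows
are r·z_standardized + √(1−r²)·ε, giving an exact population correlation with
the target Z profile.

The default demo study: 2,000 genes, 24 arrays, two planted 8-mer CREs at
carrier fraction 0.15 (CACGTGTC inducing arrays 1–2; CGCCGCCG suppressing
arrays 3–4; Δ = 1.5, responder fraction 0.5, noise and baseline sd 0.5), 20
strong TFs at population r = ±0.8 plus 30 decoys.  The ±0.8 target reflects
the sampling error of r at only 24 arrays (Fisher-z sd ≈ 0.22): a desk-scale
demo needs truly strong TFs to make "strong" calls reliable, whereas the
231-array TF-recovery experiments use r = ±0.6.

What the generator does **not** emulate: array–array correlation structure
(real meta-matrices of pooled experiment series have plenty), probe-level
microarray noise, overlapping or nested genes, repeats, or realistic genome
composition beyond order-1 statistics.  Passing tests therefore demonstrate
correctness and calibration of the machinery under clean independence
assumptions, not performance on real meta-databases, where correlated arrays
inflate effective significance and raw per-array p-values should be read
accordingly.

## Numerical and design choices

* Chi-squared p-values come from `scipy.stats.chi2.sf`; t p-values from
  `scipy.stats.t.sf`.  P-values are floored at 1e-300; backgrounds with
  p_target = 0 but observed > 0 are flagged `impossible_under_background`.
* k-means for co-expression seeds: each restart initialises from k distinct
  rows drawn by the seeded generator, 100-iteration cap, relative inertia
  tolerance 1e-8; 10 restarts, lowest inertia wins (a single random-row init
  is prone to local optima even on cleanly separated profiles).  Genes with
  > 50% missing cells are dropped; the rest are mean-imputed per array for
  distance only.
* The pipeline's default discovery budget (one motif per cluster, 150
  iterations × 6 restarts, clusters capped at 200 sequences) is the
  desk-scale default; the library function's own defaults are 200 × 10 and
  uncapped, and all knobs are exposed in the config.
* CRE naming: `OS_<AA>_<NNN>` with AA ∈ {1K, 3K, 5U, UT, 1D} by region kind
  and NNN the discovery order, zero-padded.

## Known limitations

* The combined differential-expression test is binary (I+S vs N) by default;
  the three-category reading is available but changes df and p-values.
* Copy-number counting includes overlapping occurrences; for
  self-overlapping patterns (e.g. poly-A runs) copy numbers are larger than a
  non-overlapping count would give.
* The Gibbs sampler models exactly one motif width per run; a width range
  means multiple runs.
* Despite the phase-shift moves, a discovered consensus can occasionally sit
  one register off the true word (tagging the same site set); downstream
  comparisons of discovered to expected patterns should allow a ±1-base
  alignment offset.
* Upstream flanks may include neighbouring genes' sequence on dense genomes.
* Autoregulation flags require the TF to be present in the scanned
  annotation; TFs absent from it get a missing flag, not `False`.
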