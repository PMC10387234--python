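# Methods

## Scope and data model

The package analyses serum small-RNA sequencing of three groups of
libraries — seronegative RA (N-RA, 12 libraries), healthy controls (HC, 9)
and seropositive RA (P-RA, 9) in the default design — and validates
candidates by qPCR. The unit of quantification is the *clean tag*: a read
that survived quality filtering, adapter trimming and 18–30 nt length
selection. Counts live in a miRNA × sample integer matrix together with
per-sample clean-tag totals; the totals are the TPM denominators and
include non-miRNA clean tags (contaminant classes and unannotated
sequences), i.e. "total clean data" is taken literally rather than as
miRNA-mapped tags only.

## Read processing

Raw reads pass two independent discard rules, both configurable: a read is
dropped when its fraction of `N` bases exceeds 10% (strict inequality), or
when more than 10% of its bases fall below Phred 5. A read failing both is
attributed to the poly-N counter. The 3' adapter is removed by the longest
suffix of the read that exactly matches a prefix of the adapter with at
least 6 bases; reads without a detectable adapter are kept untrimmed and
almost always fall to the length filter, which retains 18–30 nt inclusive.
Identical sequences are collapsed to tags and annotated by exact,
alphabet-normalised (U→T) match: contaminant classes
(rRNA/scRNA/snoRNA/snRNA/tRNA) take precedence over mature-miRNA identity,
and anything else is unannotated. Exact matching is sound because
references are required to be substring-free; the generator enforces this
by rejection sampling, and annotation raises an integrity error on
duplicate mature sequences. Offset/isomiR-tolerant matching is deliberately
not attempted.

## Normalisation and the zero floor

Per-sample TPM is `count / clean_total x 1e6` with no flooring. Group TPM
is computed from **pooled** group counts over pooled group totals, not as a
mean of per-sample TPMs; this matches the one-value-per-group reporting
convention and is consistent with the pooled differential test below.
Values that are exactly zero are replaced by the floor 0.01 so that fold
changes remain defined; positive values below 0.01 (possible at large
pooled depths) are reported unchanged. The heat-map matrix is the per-miRNA
row standardisation of log2(TPM + 0.01) with population SD; zero-variance
rows map to zeros.

## The exact differential test

Replicates are pooled within groups — counts and clean totals summed — so
the two-library statistic applies to replicated designs. Conditional on the
first group's count x, the second count y follows

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

equivalently NB(x+1, N1/(N1+N2)). The implementation works entirely in log
space via log-gamma. The lower tail C sums y+1 terms directly; the upper
tail D is summed forward in chunks and truncated when a certified geometric
remainder bound (the term ratio (x+k+1)/(k+1)·N2/(N1+N2) is eventually < 1
and decreasing) falls below 1e-15 of the accumulated mass, so both tails
are direct sums free of cancellation.

The two-sided p-value doubles the smaller inclusive tail. Because
inclusive-tail doubling is not symmetric under relabelling the two
libraries (the observed point's mass enters the two orientations
differently), the test is evaluated in both orientations and the smaller
doubled tail is reported. This makes the p-value exactly invariant under
swapping the groups — a property the rest of the pipeline relies on (a
differential table for A vs B and B vs A must agree) — at the cost of
deviating from the single-orientation value by at most the observed point's
probability, which is negligible at sequencing depths. One-sided lower and
upper variants are available. p-values within 1e-12 of 1 are snapped to 1,
reflecting the ~1e-15 accumulation error of the tail sums.

Selection follows the classic screen: |fold change| >= 2 on floored group
TPMs (inclusive) and p < 0.05 (strict). BH q-values are reported but do not
enter the selection rule, since the screen is defined on raw p. Output
tables are sorted by p, then |log2fc| descending, then miRNA id.

## Targets, enrichment, qPCR

Per-source target predictions (the file contract covers tools such as
RNAhybrid, PITA, Miranda, TargetScan) are intersected: a gene counts as a
consensus target when >= `min_sources` sources predict it, defaulting to
all sources. Venn regions are computed on per-source gene universes pooled
across miRNAs. The regulatory network is the bipartite edge set from
differential miRNAs (each carrying its up/down call) to their consensus
targets.

Enrichment is one-sided over-representation: P(X >= k) under
Hypergeometric(N, K, n), computed with scipy's log-space routines and
BH-adjusted across tested terms (column `q_bh`, so raw-p readings remain
possible). The background defaults to the annotation universe and can be
overridden. No ontology-graph propagation is performed.

qPCR: dCt = target Ct − reference Ct per sample; ddCt subtracts the mean
dCt of the calibrator group (HC by default — configurable, since different
studies calibrate differently); relative expression is 2^−ddCt, assuming
amplification efficiency 2. Group comparison is an ordinary one-way ANOVA
on per-sample log2 folds (the mean ± SEM reporting scale); all-equal
constant input is reported as F = 0, p = 1, and zero within-group variance
with unequal means as F = inf, p = 0.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the study inputs: a
substring-free mature reference (18–25 nt) with the five contaminant
classes; negative-binomial counts with mean
`baseline x library_size/mean_size x fold` and variance `mu + phi mu^2`
(phi = 0 is Poisson, the model under which the exact test is exact;
phi > 0 probes robustness); adapter-ligated 50 nt reads (mature + TruSeq
small-RNA 3' adapter, truncated), contaminant reads filling the library to
its clean total, and junk reads carrying exactly one QC failure mode each
so filter attribution is testable; target lists with a constructed
consensus core; term annotations; and Ct tables built so the expected ddCt
equals the injected log2 fold (exact at zero noise). Everything is
deterministic per seed, and the truth (spiked ids, folds, library sizes)
is emitted alongside.

Not emulated: sequencing error, isomiRs, precursor/hairpin structure,
genome alignment, GC or ligation bias, and real miRBase/Rfam content.
Passing round-trip and recovery tests therefore demonstrates correctness of
the bookkeeping and statistics, not robustness to real-data artefacts.

Default scales: simulation-only studies (error-rate checks) use pooled
depths of 1e6 clean tags per group, in the plausible range for serum
small-RNA libraries; the read-level end-to-end run defaults to ~2e4 tags
per library (30 libraries, ~11 s) so that full-pipeline demonstrations and
manifests stay interactive — statistical behaviour at depth is covered by
the count-level simulations, which are cheap at any depth.

## Numerical and design choices

- Tail truncation 1e-15 (relative, certified bound); p snapped to 1 within
  1e-12; all probability work in log space.
- The ambiguous QC phrasing ">10% poly-N and <5% Phred" is implemented as
  two symmetric rules (N-fraction > 0.10; fraction of bases below Phred 5
  > 0.10), each threshold exposed in configuration.
- Library-size variation in simulation: uniform 0.8–1.2 × the configured
  size.
- Published tables ship with the package at their printed precision; the
  replay tolerance in the acceptance tests is the propagated half-ulp
  bound of the printed decimals (floor cells `0.01` are exact), i.e. the
  tightest tolerance the printed inputs mathematically support.
- Ties in sorted outputs are broken lexicographically by id for
  diffability; manifests record SHA-256 hashes of every output.

## Known limitations

The pooled exact test ignores biological replicate variance — with real
overdispersed groups it is anticonservative relative to replicate-aware NB
models (that trade-off is inherent to the method implemented, and the
generator's dispersion knob makes it visible). Exact-match annotation
undercounts miRNAs with sequencing errors or isomiR variation. Consensus
intersection inherits the biases of the upstream predictors and cannot be
validated against live databases offline.
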