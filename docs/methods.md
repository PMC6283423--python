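# Methods

## Coordinate and scanning conventions

All transcript-space coordinates are 1-based inclusive in transcript
orientation; GTF input is read as 1-based inclusive and BED-like/bedGraph
inputs are converted on read. The CDS interval includes the stop codon.
Coding transcripts whose CDS length is not divisible by 3 or does not end in
a stop codon are dropped with a logged reason rather than aborting a run;
transcripts without an annotated 5′UTR are retained and simply contribute no
uORFs. Soft-masked bases are uppercased on load, and any candidate codon
containing N matches nothing.

A uORF requires its start codon to lie entirely within the 5′UTR and takes
its **first** in-frame stop codon — the stop translation would actually
reach — which must end at or before the CDS end. Candidates whose first
in-frame stop falls beyond the CDS end are discarded entirely, not
truncated. Topology is `upstream` (stop before the CDS start),
`shared_stop_extension` (frame 0, stop identical to the CDS stop — an
N-terminal extension, removed during cleansing because it can retain main
protein function) or `cds_overlap` (out-of-frame stop inside the CDS).
Identity is the genomic key (contig, strand, start first base, stop third
base) plus a fingerprint of splice junctions inside the span, so spliced
uORFs with equal endpoints but different intron structure stay distinct.
On duplication across isoforms the lexicographically smallest transcript id
is the representative — an arbitrary but deterministic tie-break.

Distance conventions: "distance to CDS" is `CDS start − stop-codon end`
(2 nt when the stop ends at transcript position 9 and the CDS starts at 11);
"distance from cap" is `start position − 1`; internal starts are counted as
near-cognate 3-mers at any offset ≥ 2 within the uORF, any frame.

## Labeling

A uORF is detected by an experiment iff that experiment has a TIS call
within ±1 nt of the start-codon first base on the same strand; the window is
configurable, but ±1 matches the start-codon resolution of
initiation-arrested profiling and the rule used for lncRNA ORF calls
(translated at ≥10 reads summed within ±1 nt of the start). Literature
positives count as one additional vote source by default; an optional flag
promotes them straight to 2-voted, since the published wording is ambiguous
on this point. Ribosome binding strength is reads at the start codon divided
by transcript expression; "strong" means strictly above the
linear-interpolation median among positives, so a degenerate all-equal
distribution is all-weak.

## Discretization and feature ranking

MDLP discretization recursively accepts the information-gain-maximizing
binary cut iff the gain exceeds the Fayyad–Irani minimum-description-length
threshold `(log2(N−1) + log2(3^k−2) − [k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)])/N`.
Candidate cuts are midpoints between adjacent distinct values; ties on gain
break toward the smallest cut, making the scheme deterministic. Features
with no accepted cut fall back to a single bin and are flagged; categorical
features (start codon) bypass MDLP with one bin per category. Feature
prioritization uses the two-sample Kolmogorov–Smirnov statistic between
positive and unlabeled values (scipy), which is invariant under monotone
transforms and hence insensitive to feature scaling.

## Positive-unlabeled naive Bayes

Likelihoods are add-k smoothed bin frequencies (k = 1 by default, keeping
every bin strictly positive so the log-odds is finite). Scores are computed
in log space; a missing value skips that feature's factor, which the
factorization permits; a category unseen in training is clamped to the
nearest bin and counted on the model. The decision threshold is score > 0
with strict inequality (deterministic tie-break, measure-zero in practice),
and natural log is used — the zero threshold is base-invariant. Training
positives default to the 2-voted set; the 1-voted set is left as a soft
evaluation set. The prior grid for F1 maximization is 0.01…0.99 in steps of
0.01 with ties to the smallest value; 0.61 is recorded as the published
genome-scale operating point and used as the scoring default.

Leave-one-experiment-out validation trains on positives defined from the two
retained experiments — default "either" (detected in ≥1 of them), with a
"both" mode available — returns the held-out experiment's detections to the
unlabeled pool, and evaluates retrieval of those detections among all
non-training examples by ROC AUC (trapezoid). The prior shifts all scores
equally and therefore does not affect AUC.

The peptide score applies the same machinery to peptide length, the 20
amino-acid frequencies and a mass-spectrometry evidence flag, and is
reported separately, never folded into the main score. MS evidence is exact
substring matching of supplied peptides against the uORF's in-frame
translation, excluding peptides that also occur in any CDS translation; this
replaces a BLAST search with an exact-match criterion that enforces the same
frame-fidelity and no-gap constraints in-process.

## Mark-recapture population estimation

Experiments are treated as sequential samples from one closed population;
`series_from_sets` derives `C_t`, cumulative marked `M_t` and recaptures
`R_t` from detection sets keyed by unique genomic coordinates (so a uORF on
several transcripts is one animal). The Schnabel estimator is
order-dependent, so `estimates_all_orders` reports all six orders of three
sets alongside the Schumacher–Eschmeyer estimator; on the published
three-study aggregates the spread is ~8.3–8.8 thousand, consistent at order
of magnitude with the published round figure of ten thousand. The overlap
solver inverts the linear system relating per-set "found in ≥1 other set"
counts to pairwise intersections and verifies inclusion–exclusion against
the stated union exactly, raising on any residual. Zero recaptures make an
estimate infinite and raise rather than return a number.

## Variant impact

Losses are SNVs inside the start codon of a predicted-positive uORF whose
substituted codon leaves the permitted start set (all 10 codons by default;
note ATG itself cannot be lost by a single substitution under the full set,
since every single-nucleotide variant of ATG is near-cognate — the
restricted {ATG, CTG} subset is the configuration under which ATG loss is
meaningful). Gains require a complete new uORF — the created ATG/CTG (by
default) must have an in-frame stop before the CDS end — and, when a scoring
callback is supplied, a positive classifier score. Minus-strand alleles are
complemented before codon arithmetic, and a reference-allele mismatch with
the genome skips the variant with a warning (assembly check). Indels are
counted and deferred to a secondary channel because they superpose competing
effects. The density matrix is defined over interruption (loss) events:
reference start codon × (codon position 1–3 × alt base), identity cells
structurally zero.

The expression contrast is a pooled-variance two-sample t at the
observation level — one observation per (variant, carrier individual) —
restricted to variants carried by more than the sharing threshold
(default 10) of individuals; this observation unit is a reconstruction
choice consistent with the published degrees of freedom. A secondary
contrast splits loss events by uORF topology (CDS-overlapping vs fully
upstream) to probe uORF–uORF repression. rQTL enrichment is the observed
fraction of variants hitting positively scored starts versus the
genome-wide positive fraction, with a two-sided exact binomial test.

## Synthetic data

The generator has two layers sharing one `SimulationConfig`.

The **statistical catalog** draws 20,000 uORFs with 1,000 truly active
(5%), observed by three pseudo-experiments with per-uORF detection
sensitivity 0.40 and false-positive rate 0.001 — the high-false-negative,
high-specificity regime in which roughly `1 − (1 − s)² ≈ 64%` of detected
uORFs are re-found elsewhere at perfect features, and far fewer in
practice. Active uORFs draw conservation at start/stop codons from
N(2.0, 1)/N(1.5, 1) versus N(0, 1); exponential CDS distances with means
203 versus 318 nt and 5′UTR lengths centred at 360 versus 618 nt (the
published positive/unlabeled means); Poisson internal-start counts 2.0
versus 3.0; a start-codon distribution favouring ATG/CTG among actives; and
only a mild context-score shift, so that conservation and position — not an
invented context feature — carry the signal. GC content and uORF length are
deliberately uninformative controls.

The **file bundle** plants one uORF of known activity per transcript in a
single-contig mini-genome (default 200 transcripts; tests and the
acceptance script use 60–120), with UTR/CDS-distance scales reduced fourfold
to keep sequences small, planted bodies free of in-frame stops so the
planted stop is the first reachable one, per-base conservation over UTRs,
TIS tables from the same sensitivity model, MS peptide fragments from a
subset of active uORF translations, a VCF of constructed loss and gain SNVs,
a genotype matrix over 46 individuals (carrier probability 0.35) and
per-gene protein levels with planted effects +0.5 SD for gain and −0.5 SD
for loss carriers. Bundles are byte-identical under a fixed seed.

What the generator does **not** emulate: read-level profiling data and
P-site offsets, real codon usage and Kozak statistics, isoform complexity
beyond simple splicing, correlated features, linkage between variants, and
population structure. Passing tests therefore demonstrate correctness of the
pipeline's computations and its qualitative behaviour under the stated
sampling model, not performance on real genomes; in particular the
synthetic leave-one-out AUC (~0.9 at default conditions) is an upper bound
produced by independent features, comparable in kind but not in difficulty
to published cross-experiment AUCs near 0.8.

## Problem sizes and numerics

Default test-time sizes — 200 random transcripts for the scanner oracle,
catalogs of 20,000 for classifier experiments over 5 seeds, 20-seed
recovery simulations, 10-seed variant sign recovery on 60-transcript
bundles — run in well under a minute each and were chosen as the smallest
scales at which the stochastic bands are stable. Likelihood normalization is
validated to 1e-9; overlap solving is exact linear algebra on 3×3 systems;
ROC curves use scikit-learn; the binomial and t tests use scipy.

## Known limitations

The published genome-scale counts (≈1.27 M unique uORFs, ≈189 k predicted
positive) require GENCODE-scale annotation plus real conservation and
profiling tracks and are not reproduced here, though the same code paths
support such a run. The 89-attribute panel of the original analysis is
represented by the ~12 attributes named in the main analysis plus an
extension interface (`FeatureDef`); repeat-associated non-ATG translation,
RNA-editing-created uORFs and CDS-internal ORFs are out of scope.
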