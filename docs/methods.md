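# Methods

`ptcscape` reconstructs the in vivo fitness landscape of the peptidyl
transferase center (PTC) and exit-tunnel entrance of an orthogonal tethered
ribosome (oRiboT) from paired positive/negative selection sequencing data.
Because the engineered ribosome translates only orthogonally tagged mRNAs,
its PTC can be saturated with mutations — including otherwise dominant-lethal
ones — and both enrichment of functional variants (positive selection, oCAT /
chloramphenicol survival) and enrichment of impaired variants (negative
selection, toxic oEcoRI translation) can be read out by sequencing the
mutagenized window before and after selection.

## Library designs and coordinates

A `LibraryDesign` is a contiguous window of 5–6 fully randomized positions in
1-based E. coli 23S rRNA numbering, with wild-type bases stored as RNA and
the amplicon context (flanking anchors, condition barcodes) as DNA. Six
built-in designs cover 2058–2062, 2447–2451, 2495–2499, 2500–2504, 2503–2507
and 2583–2588 (diversities 4^5 = 1024 and 4^6 = 4096). Wild-type identities
carry a per-position provenance flag: positions whose identity the underlying
study names are flagged `named`; the remainder (2447, 2449, 2496–2499, 2506,
2588) are filled from the E. coli 23S reference and flagged `reference`, and
can be overridden by a user config. The amplicon anchor sequences are not
published; the bundled anchors are synthetic fixtures.

## Selection and sequencing simulator

The simulator is the package's stand-in for raw data and defines the
conditions under which every end-to-end guarantee is tested.

* **Truth model.** Multiplicative per-position preferences (WT base = 1)
  with optional pairwise couplings:
  `w(v) = Π_i pref[i][v_i] × Π_{i<j} coup[(i,v_i),(j,v_j)]`.
* **Selection.** One-step exponential tilt of the frequency vector,
  `freq' ∝ freq · w^{+s_pos}` (positive) or `freq · w^{-s_neg}` (negative),
  computed in log space. This collapses the study's serial growth
  competition + FACS sort into a single tunable filter per arm; the two
  arms default to equal strength (s_pos = s_neg = 1) since their relative
  stringency is not quantified.
* **Sequencing.** Multinomial sampling of read pairs from the
  post-selection frequencies at a configurable depth (conventionally quoted
  per variant per condition), followed by independent per-base substitution
  errors (no indels — with fixed-length windows located by anchors,
  substitutions are the only error mode the extractor must tolerate).
  Read layout: R1 = forward barcode + upstream anchor + window +
  downstream anchor (+ reverse-barcode complement); R2 is the reverse
  complement. One root seed; each (condition, purpose) pair derives an
  independent child stream, so FASTQ output is byte-reproducible.
* **Initial composition.** Uniform by default; a Dirichlet-skewed mode
  emulates biased naive libraries from different cloning routes.

Reference truth models:

* `benchmark_truth` — the fixed "scattered severity" landscape used for
  parameter-recovery checks: a few severely deleterious bases with distinct
  severities at distinct positions (2×10⁻⁴ … 8×10⁻³) and graded mild costs
  elsewhere. No position is uniformly lethal, but multiply-mutated variants
  compound to a deep lethal tail. See *Why the benchmark looks like this*
  below.
* `lethal_position_truth` — all non-WT bases at one position set to a
  preference of 10⁻⁶, everything else neutral (the dominant-lethal-position
  scenario, e.g. A2060).
* `coupled_truth` — plants a single pairwise coupling on a base landscape.

What the simulator does **not** emulate: PCR jackpots and chimeras, FACS
gate geometry, growth kinetics, indels, batch effects between replicate
selections. Passing recovery tests therefore demonstrates the analytic
pipeline is correct and well-conditioned under multinomial sampling noise,
not that real selections are free of these artifacts.

## Read processing

Per read pair: (1) mean-Phred filter per mate (default ≥ 20, inclusive);
(2) demultiplexing by the published condition barcodes, anchored to a
read-start window (barcode length + 2 bases, ≤ 1 mismatch, both mates must
agree; ties and failures are tallied, not errors); (3) window extraction by
locating the upstream anchor (≤ 1 mismatch), taking the next k bases and
verifying the downstream anchor, independently in R1 and in the reverse
complement of R2 — if both mates cover the window and disagree at any base
the pair is discarded as `ambiguous`; (4) exact-sequence counting (the
window is ≤ 6 nt and depth per variant is high, so no error
correction/clustering is warranted). The accounting identity
`reads_in = counted + fail_quality + no_barcode + no_anchor + ambiguous`
holds for every run and is asserted in tests. The forward-barcode-on-R1
convention is an assumption; `swap_mates` flips it.

## Enrichment and fitness

Counts are converted to per-condition abundances with a pseudocount
(default 0.5) added to **every** variant of the design before normalizing to
frequencies (sum 1; a reads-per-million mode exists). Enrichment is the
signed difference against the unselected population, `Ap − A0` and
`An − A0`. Fitness is the enrichment ratio

    oriented (default):  f = (Ap − A0) / (A0 − An)
    literal:             f = (Ap − A0) / (An − A0)

The oriented form makes variants enriched in the positive arm and depleted
in the negative arm score positive, matching the validated sign semantics
(high reporter signal ↔ high fitness). Values with |denominator| below
`denom_tol` (10⁻⁶ in frequency units) are missing, excluded from all
downstream statistics. Raw fitness is z-normalized per library using the
population (ddof = 0) SD, configurable.

**The ratio statistic is intrinsically non-monotone.** A variant enriched in
the negative arm has A0 − An < 0, and if it is also depleted in the positive
arm the two negative signs cancel: strongly nonfunctional variants land on a
*positive* branch of f interleaved with functional variants. Such variants
are flagged `discordant`. The practical consequence: rank recovery of true
fitness is excellent when the landscape has a deep, heterogeneous lethal
tail (which dominates the negative arm and pushes the ratio's singularity
below essentially every variant) and degrades when many variants sit near
the singularity — weak-effect landscapes are the worst case, and landscapes
with an entirely lethal position put ~¾ of the library into a regime where
positive- and negative-arm information cancels. This is why
`benchmark_truth` is shaped the way it is: it is the realistic regime (most
PTC mutants are strongly deleterious, severities vary over orders of
magnitude) in which the estimator provably behaves, and under it the
pipeline's z-fitness achieves Spearman ρ ≈ 0.88 against log true fitness at
200× depth (measured stably across 20 independent sampling seeds).

A normality summary (moment skewness and excess kurtosis of raw fitness) is
reported, not gated; the study's libraries showed approximately normal
fitness distributions.

## Mutational flexibility (Shannon entropy)

For each position, the marginal score of each base is the mean score over
all variants carrying that base (missing scores excluded). The score
defaults to positive-arm enrichment `Ap − A0`; z-fitness and positive-arm
abundance are alternatives. Marginals are converted to base probabilities
with the positive-part rule — negative marginals get probability 0, positive
ones are renormalized, and if no marginal is positive the most favored base
takes all mass (ties broken A<C<G<U) — then

    H(X) = −Σ_b P(b) log2 P(b)   ∈ [0, 2] bits,

0 = exactly one tolerated base, 2 = all four equally tolerated. A softmax
probability mode (temperature τ) is available for sensitivity analysis.
Classification: H < 0.3 low, H > 1.3 high, otherwise intermediate — the
cutoffs are package conventions (the study shows a color scale, not
numbers) and are configurable.

Two deliberate choices here:

* **Default score = positive-arm enrichment, not z-fitness.** In the
  lethal-position scenario the ratio fitness assigns nearly identical values
  to lethal and functional variants (both arms' information cancels — see
  above), so z-based marginals at the lethal position are noise; enrichment
  marginals separate cleanly (the lethal position's non-WT marginals are
  robustly negative) and reproduce the "entropy exactly 0 at a dominant
  lethal position" behavior.
* **Zero-sum caveat.** Any score that sums to ~0 over the library
  (enrichment, z) has class means at *neutral* positions that are zero in
  expectation, so the positive-part probabilities there are sign-of-noise;
  entropies at truly neutral positions are not stable under these scores.
  The frequency-style reading (`score="abundance_pos"`: marginal = mean
  positive-arm abundance, whose positive-part normalization equals the
  post-selection base frequency at the position) reports H = 2 at neutral
  positions robustly and ≈ 0 at lethal positions, and is the mode the
  neutral-position tests use.

The pairwise map generalizes marginals to ordered position pairs: a 4×4
matrix of mean scores per base combination, with empty combinations NaN.
`structure_annotation` exports a flat (position, entropy, class) TSV for
coloring a 3D structure viewer by residue number; no structural computation
is performed.

## Pairwise epistasis

Over single and double mutants of the WT window only,

    ε = f(AB) − f(A)·f(B)

per ordered pair (posA < posB, both bases non-WT): C(k,2)·9 entries per
library, missing when any constituent fitness is missing, never imputed.
Because the ratio fitness can be negative while a product null needs a
nonnegative scale, fitness is rescaled per library before applying the
null — `unit_interval` (affine to [0,1], default) or `wt_relative` (shift so
the minimum is 0, divide by the shifted WT value, so WT → 1) — and the
rescale anchors on the Hamming ≤ 2 subset that actually enters the analysis
(library-wide anchoring would let near-singularity variants with |f| in the
hundreds dictate the scale). ε values are then z-normalized per library by
mean and SD, i.e. the product null is applied on the rescaled (not
z-normalized) fitness and normalization happens afterwards.

In the deep-tail regime the oriented fitness is approximately affine in w
with f(dead) ≈ −1, so the shifted rescale makes scaled fitness approximately
*proportional* to w and a multiplicative truth yields ε ≈ 0: noiselessly at
10⁴× depth the benchmark landscape gives max |ε_raw| ≈ 0.008. A planted
coupling of 8 (or 1/8) between two moderately tolerated bases produces the
library's maximal (minimal) ε_z at the planted cell with |ε_z| ≈ 7–8 at
500× depth, stable across seeds. On a *neutral* background the enrichment
denominators are pure noise and no epistasis signal is recoverable — the
recovery harness therefore always plants couplings on the benchmark
landscape.

## Numerical conventions

* Selection tilts computed in log space (preferences may span 10⁻⁶ … 10).
* Entropy: 0·log 0 = 0; probability vectors validated to 10⁻⁶; −0.0
  normalized to 0.0.
* z-scores: population SD; degenerate (zero-SD) libraries raise.
* Pseudocount 0.5 applied to all 4^k variants, so absent variants have
  defined abundances in every condition.
* Seeds: `SeedSequence([root, condition_index, stream])`; byte-identical
  FASTQ for identical seeds.

## Problem sizes used by the test and acceptance runs

Stochastic guarantees run on the 2058–2062 design (1024 variants) at the
depths stated with them: 500 reads/variant/condition for lethal-position
entropy and coupling recovery, 200 for rank recovery, 10⁴ (noiseless
expected counts) for the multiplicative null. Brute-force oracle
comparisons use k ≤ 3 toy designs where full enumeration is trivial.

## Known limitations

* The enrichment-ratio fitness conflates strongly nonfunctional with
  functional variants outside the deep-tail regime (flagged, documented
  above); a log-ratio statistic would be monotone but would not be the
  statistic this package reconstructs.
* Entropies computed from zero-sum scores are unstable at selectively
  neutral positions (rare in the PTC, but real).
* No per-variant uncertainty: point estimates only, matching the upstream
  analysis; bootstrap resampling of reads would be a natural extension.
* Epistasis is within-library only (≤ 6 nt windows); interactions across
  library boundaries are invisible by construction.
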