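# Methods

This note records the models, conventions and numerical choices behind
`probeval`, and what the synthetic benchmarks do and do not demonstrate.

## Reactivity model

Reactivity is the raw per-position event rate of a probing experiment:
mutations / covering reads (MaP) or recorded RT stops / informative
reads (SEQ), where a read is informative at a position if its cDNA
covers or terminates there. No normalization (winsorizing, 2–8%
scaling) is applied anywhere: every downstream statistic (ROC, top-x%)
consumes ranks or raw rates, and normalization is rank-preserving
per molecule, hence irrelevant to the evaluation and a source of
cross-study incomparability.

A note on the stop-rate denominator: dividing the stop count by itself
would be identically 1, so the denominator is necessarily the
informative-read count — the standard RT-stop convention. This is the
module's central interpretive decision and is asserted by the rate
tests.

Background adjustment is the plain difference `rate(+) − rate(−)`.
Negative differences are kept by default (clamping to zero is optional)
because subtraction order statistics feed the ROC and clamping would
merge distinct ranks at zero.

Filters follow the transcriptome-scale conventions: coverage strictly
over 500 reads (501 passes, 500 does not), DMS restricted to A/C,
SHAPE keeping all four bases, and an mRNA analysed only when at least
50 positions pass the coverage filter. Positions failing any filter
carry an explicit invalid flag (NaN reactivity) rather than a zero, so
they can never leak into rankings.

## Structure concordance

The positive class is the **unpaired** base (a dot in the reference
dot-bracket); reactivity is the score. The ROC is built from first
principles by a descending threshold sweep with tied scores grouped, so
the trapezoidal AUC equals the Mann–Whitney statistic with half credit
for cross-class ties; the suite verifies this identity against a
brute-force pairwise count (to 1e-12 on hundreds of tied instances) and
against scikit-learn as an independent library cross-check.

Pseudoknot bracket layers (`[]`, `{}`, `<>`) parse with per-layer
stacks and count as "paired"; the evaluation never needs to know which
layer a pair came from. Non-canonical and wobble annotations are
likewise treated uniformly as paired.

Top-x% selection takes the ceil(x/100 · n_valid) highest-reactivity
valid positions with ties broken by ascending position index — a
deterministic rule chosen purely for reproducibility. Ranking is
per-molecule by default (reactivity scales are not comparable across
molecules); a pooled mode exists but is non-default. Histogram bins are
half-open [a, b), with explicit overflow (≥ range_max) and underflow
(< 0, possible after unclamped subtraction) pools.

## Ensemble pairing probabilities

Imported base-pair probability matrices are plain `i j p` TSV; marginals
m[i] = Σ_j p[i][j] may exceed 1 by at most 1e-6 (import rounding) and
are clipped, anything larger being rejected as inconsistent. The
built-in toy ensemble enumerates every nested structure with hairpin
loops ≥ 3 and canonical + wobble pairs (length guard 30), weighting
structures by w^#pairs. It exists as an exactly checkable oracle for
marginalization and flagging — it does not emulate any thermodynamic
parameter set, and w is accepted for any positive value (w = 1 is the
uniform ensemble used in the oracle tests; w → ∞ concentrates on
maximally paired structures). Discordance flagging combines an
inclusive marginal threshold (≥ 0.995 by default) with membership in
the top-10% reactivity set, using the same deterministic top-k rule as
above.

## Solvent accessibility

Shrake–Rupley with van der Waals radii C 1.70, N 1.55, O 1.52,
P 1.80 Å (overridable; unknown elements require an explicit radius) and
a default probe radius of 3 Å — the size regime of a probing reagent
rather than a water molecule. Test points are a deterministic
golden-spiral lattice (960 points by default; 4π(r+p)² is reproduced
within 1% at 960 and 0.2% at 10 000 points). The lattice is oriented in
a molecule-fixed principal-axes frame with third-moment sign fixing, so
areas are invariant under rigid rotation/translation to ~1e-6 relative;
for exactly symmetric point sets with degenerate principal spreads the
frame is arbitrary but still deterministic. Burial uses a strict
"inside" test with a 1e-9 Å² guard band: a point exactly on a
neighbour's expanded sphere is exposed, so coincident equal-radius
atoms do not occlude each other — a documented convention, not an
accident of rounding.

Relative accessibility divides a residue's in-context area by the same
residue's area computed in isolation (all other residues deleted); this
normalization is recorded in the output metadata so users can
substitute fixed per-nucleotide maxima. Residues missing from the
coordinate model are simply absent and excluded from correlations, and
a per-chain integer offset maps model residue numbering onto reference
positions (no automatic alignment is attempted). Correlations are
Pearson r over the chosen subset (all / top10 / bottom90 by reactivity
rank; paired / unpaired given a reference structure), refusing subsets
with fewer than three points or zero variance.

## Simulator

Each molecule is modified independently at position i with probability
m_i; `target_mods_per_molecule` rescales m to a single-hit budget
(≈ one modification per ~200 nt) rather than truncating, since SEQ
censoring already caps observed stops at one per molecule. In SEQ mode
reverse transcription initiates at the 3' end and terminates at the
3'-most stop event — the modification censoring that produces the 5'
detection bias — with natural stops at a per-position rate during the
walk; the stop is recorded at (modified position + offset), offset
∈ {0, +1} because protocols differ on the assignment convention
(default 0: the evaluation indexes the modified base). A +1 offset on a
3'-terminal stop falls off the molecule: no event, full-length-looking
read. Depth at p counts molecules whose walk reached p (cDNA spans
[stop, L]). MaP reads are full length; a mutation is recorded unless
both detection (probability `mutation_detect_prob` per modification)
and sequencing error (rate `seq_error_rate`) fail. The minus channel is
the identical machinery with m ≡ 0. All draws flow from one seed
through fixed-size (20 000-molecule) chunks with separate seeded
streams per channel, so outputs are bit-stable.

`expected_rate_profile` gives the closed form: MaP
E[rate] = d + (1−d)e with d = m·detect; SEQ from the censoring model
via survival products (the ratio of expected events to expected depth,
which empirical rates approach in the large-sample limit — at 1e5
molecules the empirical rates sit within 3 binomial SE of it at ≥ 99%
of covered positions).

### Benchmark scenarios

All scenarios use a deterministic 200-nt structure of eleven 18-nt
hairpin units (5-bp GC stem, 5-nt loop, 3-nt linker) plus a 2-nt tail:
90 unpaired / 110 paired positions (45% unpaired, inside the 38–50%
range typical of reference rRNA structures).

* **separable** — MaP, unpaired m = 0.08, paired m = 0 exactly, no
  errors, 1e5 molecules: class rate distributions are disjoint, so AUC
  and the top-10% unpaired fraction are exactly 1. A positive control.
* **overlap** — MaP with per-position modification levels cycled
  deterministically over each class (unpaired: 0, 0.02, 0.05, 0.10;
  paired: 0, 0, 0.01, 0.02), 1e5 molecules. The shared low levels make
  the class distributions genuinely overlap while most of the profile
  stays near zero (roughly two-thirds of bases below rate 0.02, ~4–7%
  above 0.1) — the qualitative shape of real transcriptome-scale data,
  where ~90% of bases are near zero and high-reactivity bases are rare
  but structurally informative. The deterministic stratified level
  assignment (rather than random draws) removes assignment noise, so
  the simulated AUC tracks the exhaustive binomial-mixture oracle
  within well under ±0.02 at L = 200. Sequencing error is zero here so
  that zero-level positions tie exactly, which the half-credit AUC
  handles deterministically.
* **background-heavy** — SEQ, natural stop rate 0.02 against
  modification signals of 0.008/0.001, 2e4 molecules. The background is
  positionally uniform, so subtracting its *expectation* would not
  change ranks at all; subtracting the *noisy per-replicate estimate*
  (independent between channels) only injects variance and degrades
  the AUC — plus-only wins in ≥ 8 of 10 seeded replicates. Parameters
  were sized so background sampling noise is comparable to the class
  separation; with negligible background the two pipelines coincide and
  the comparison becomes a coin flip.

### What the simulator does not model

Random priming and fragmentation (molecules are full length and
3'-initiated), PCR duplication, read-level quality, sequence-dependent
modification preferences beyond the pairing classes, structural
dynamics, and probe over-modification artefacts. Scenario background
rates are illustrative, not fitted to any real probe-free channel.
Passing benchmarks therefore demonstrates internal correctness of the
estimators and the qualitative mechanisms (censoring bias, background
noise injection, overlap-limited separability) — not quantitative
agreement with any particular organism or protocol.

## Problem sizes and determinism

Default verification sizes — 1e5 molecules × 200 nt for scenario
checks, 2e4 for the ten background replicates, 200 random ROC instances
up to n = 500, exhaustive enumeration cross-checks over all 4-letter
sequences to length 10 (via their pairability patterns) and random
sequences to length 14 — were chosen as the smallest scales at which
each property is sharp (binomial SE well below the tolerances used).
Hypothesis-based property tests run derandomized; every stochastic
computation takes an explicit seed, and the CLI records seeds and
parameters in its manifests/reports so each number is recomputable.

## Known limitations

* The three-line dot-bracket dialect is deliberately minimal; multi-RNA
  structure files are not supported.
* The toy ensemble cannot stand in for a partition-function folder on
  real sequences (no stacking energies, length-30 guard).
* SASA values are method-parameterized (radii, probe, lattice density)
  and are not expected to match other implementations' absolute values;
  only the documented invariants are guaranteed.
* The CLI writes JSON/TSV reports only; no plots are generated.
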