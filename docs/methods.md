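# Methods

## Model

A decision path — one (decision, condition) combination — is modelled as a
wave of equal frequency whose intensity equals its probability and whose
phase is a population constant. Two paths feeding the same decision
superpose, and the probability of that decision when the condition is
unknown is the resultant intensity

    p(D | unknown) = p₁ + p₂ + 2·√(p₁·p₂)·cos θ,        p_i = p(D, C_i)

This combination is deliberately **not** a normalised probability law: the
resultant ranges over [(√p₁−√p₂)², (√p₁+√p₂)²], which can leave [0, 1].
Values are returned raw with an out-of-range flag and never renormalised,
because the account gains its content precisely from the classical law
(θ = 90°) being a special case, not a constraint.

Assumptions inherited from the account being implemented:

- equal wave frequency across paths (no beat terms), so only the phase
  offset matters;
- phases are stable population constants for a given decision context,
  which is what makes prediction (rather than per-experiment fitting)
  possible;
- for electrode data, intensity ∝ amplitude² with a proportionality
  constant that cancels in the phase inversion (set to 1), and published
  component amplitudes are treated as magnitudes without polarity handling.

## Phase extraction

Inverting the combination gives
cos θ = (p − p₁ − p₂) / (2·√(p₁·p₂)). Three inversions are used:

- **cell phases θ₁…θ₄**: for each of the four (decision, condition) cells,
  the joint p(d, c) = p(c)·p(d|c) is inverted against the decision marginal
  p(d) and condition marginal p(c);
- **experimental phase θ_expt**: the observed unknown-condition probability
  is inverted against the focal decision's two joints;
- **electrode phase**: the squared neutral-class amplitude is inverted
  against the squared positive- and negative-class amplitudes.

Cell-index convention (the one that reproduces the published tables, which
the source's own four-cell notation does not):

    θ₁ = (reference, positive)   θ₂ = (alternative, positive)
    θ₃ = (reference, negative)   θ₄ = (alternative, negative)

with reference = withdraw / play-again / defect and positive = good / win /
known-defect.

## Combination rules

Fixed per-paradigm presets, applied to the cell phases:

| paradigm               | rule                    |
|------------------------|-------------------------|
| categorization (wide)  | θ_fit = 360° − (θ₁ + θ₂) |
| categorization (narrow)| θ_fit = 360° − (θ₁ + θ₄) |
| two-stage gambling     | θ_fit = (360° − θ₂)/2    |
| prisoner's dilemma     | θ_fit = (360° − θ₂)/2    |

The disjunction rule reads θ₂ as a **fixed cell**, not as "the cell with the
smallest conditional probability": in one dilemma experiment (PD6, where
cooperation under known-cooperation is the rarest choice) the two readings
disagree, and only the fixed-cell reading reproduces the published fit. A
`min_conditional_rule` helper implements the searching variant for
comparison; it is never applied by default. Similarly, the two
categorization presets are kept literal per face type rather than derived
from a single "safest + riskiest" selection principle, because no such
principle covers both face types; `custom` scenarios take an explicit
`PhaseFitRule`. Since cos(360° − x) = cos(x), the sum-complement form needs
no branch handling.

## Numerical conventions

- **Degrees everywhere** at public boundaries; radians only inside trig
  calls. Inverted phases live on the arccos principal branch [0°, 180°];
  pairwise phase differences feeding a cosine are signed, but cosine is
  even, so the branch choice is observationally irrelevant.
- **Clamping, not rejection**: an inversion cosine outside [−1, 1] (routine
  when the inputs are sample frequencies) is clamped to the boundary and
  the result flagged. Clamp flags propagate into reports; a clamped θ₂
  halves to exactly 90° under the disjunction rule.
- **Degenerate inputs**: a vanishing interfering component (zero joint or
  marginal, zero positive/negative amplitude) raises a degenerate-input
  error rather than returning an arbitrary phase.
- **Round-off at the arccos endpoints**: the derivative of arccos diverges
  at ±1, so round-trip identities are exact to 1e−9 degrees only away from
  0°/180°; the endpoints themselves are verified to a looser 1e−5 degrees.

## Summary-statistic conventions

Pinned by recomputation against the published summaries; both were checked
and the reproducing convention adopted:

- mean ± SD uses the **sample** SD (n−1); CV = sample SD / mean. The
  electrode-phase CVs reproduce only with the sample SD (population SD
  gives 0.06 instead of 0.07 for the four-electrode table).
- RMSD between θ_expt and θ_fit uses the **population** denominator N and
  is computed from phases **rounded to the printed precision** (2 dp); with
  unrounded phases the narrow-face RMSD lands at 3.71 instead of the
  published 3.70.
- MAPE uses **unrounded** fitted probabilities and divides by the
  **fitted** value. The observed-value denominator is available
  (`mape_denominator="observed"`) but gives 0.07 where 0.06 was published
  for the wide-face set.
- Excluding experiments from a summary is explicit configuration
  (`exclude=[...]`), never inferred from the data.

## Bundled tables and known discrepancies

Six published tables ship as CSV fixtures: inputs exactly as printed, plus
the printed derived columns, which are used for comparison only and never
fed back into computation. `reproduce_table` recomputes every derived cell
and compares it against print under a per-table policy, with frozen
exception lists asserted **exactly** by the test suite (a new mismatch is a
failure, and so is an expected mismatch that stops occurring):

- **categorization**: every cell matches at 2 dp; the 180.00° cells are
  recovered as clamped inversions.
- **gambling**: every cell matches at 2 dp except G2's p_fit, printed 0.40
  where the row's own printed θ_fit = 106.91° implies 0.45 — an apparent
  misprint.
- **prisoner's dilemma**: the printed inputs are evidently probabilities
  rounded from fractions over groups of 30 subjects. With printed inputs
  the most rounding-sensitive cells drift; exactly five phase cells exceed
  0.5° (PD4 θ₂ and θ_fit, PD5 θ₂ and θ₄, PD6 θ₄). Reconstructing the
  fractions (`input_set="fractions"`, nearest k/30) brings every phase cell
  within 0.1° of print except PD2's θ_expt: printed 101.29°, recomputed
  101.04° from fractions and 101.39° from printed inputs — consistent with
  a transposed digit in the source.
- **electrode tables**: printed phases derive from unrounded source
  amplitudes that were not published; recomputation from the printed
  amplitudes agrees within 0.5° everywhere (compared at a 0.6° tolerance),
  and the phase CVs round to the published 0.07 / 0.02 / 0.02.

Published summary values that recomputation contradicts (documented and
pinned in tests, excluded from exact reproduction):

- wide-face RMSD: published 4.67°, recomputed 4.47° under every convention
  tried (a 4.47 → 4.67 digit error would explain it);
- the gambling post-exclusion RMSD 6.12° reproduces when **one** experiment
  (G3) is excluded, while the companion θ_fit = 106.83 ± 3.77° needs
  **two** (G3 and G6) — the source's "excluding these two experiments" is
  internally inconsistent, so exclusion sets are caller-specified;
- the post-exclusion gambling MAPE of 0.06 reproduces under no combination
  of denominator and exclusion set (recomputation gives ≥ 0.10);
- the "< 1/59 000 000 000" five-phase clustering probability is a factor of
  10 from (2/180)⁵ ≈ 1/5.9 × 10⁹ and matches neither the naive power nor
  the exact range formula. Both formulas are provided:
  P(range ≤ w) = n(w/L)ⁿ⁻¹ − (n−1)(w/L)ⁿ exactly, and (w/L)ⁿ as the naive
  bound; the exact form dominates the naive one with equality only at
  w = L.
- θ₁ of the gambling table: published 134.87 ± **5.09°**; the sample SD of
  both the printed and the unrounded phases is 5.10.

The pooled unified-rule deviations do reproduce: 4.10° over all ten
categorization rows, and 5.96° over the disjunction experiments when the
two protocol-deviant gambling experiments are excluded and the dilemma rows
pooled.

## Synthetic generator

`SyntheticConfig` → `generate_scenario` emulates the source designs:
between-subjects groups answering one binary question each, one group per
known condition and one under the unknown condition. Defaults are the
first gambling experiment's conditions — equal condition marginals (0.5),
conditionals 0.69 / 0.57, groups of `n_subjects = 200` (typical of the
cited experiments), 500 replicates.

- **Noise-free mode** (`n_subjects=None`) sets the unknown-condition
  probability to the model's own prediction at the rule's θ_fit, making the
  generative assumption explicit; analysing such a scenario returns
  θ_expt = θ_fit to 1e−9 degrees (tested across all presets and a grid of
  conditionals).
- **Noisy mode** replaces the two conditional response probabilities and
  the unknown-condition probability by independent binomial sample
  frequencies over `n_subjects`. The condition marginal is a design
  constant set by the experimenter (the 50/50 gamble, the stated opponent
  behaviour) and is not sampled.
- **Seeding**: one integer seed drives a `SeedSequence` whose spawned
  children give each replicate its own substream, so any replicate is
  reproducible in isolation.
- **Recovery reports** (`recovery_experiment`) give bias and SD of the
  recovered θ_expt and cell phases against the noise-free truth, plus the
  fraction of replicates in which any inversion clamped. Truths near the
  180° boundary produce clamped draws and hence biased recoveries; the
  report surfaces the clamped fraction rather than correcting the bias.

What the generator does **not** emulate: within-subject designs (responses
are independent across groups by construction), individual differences or
hierarchical structure, response times, and any drift of phases across
populations. Passing recovery tests therefore show that the estimator
recovers stable phases from binomial sampling noise at realistic group
sizes — not that real populations share a phase.

## Limitations

- Two conditions and two decisions only; no continuous condition spaces.
- θ is never fitted by optimisation — the package's point is that it is
  not a free parameter; `PhaseFitRule` variants are the only degrees of
  freedom, and they are discrete and explicit.
- The electrode pipeline starts from published mean component amplitudes;
  raw EEG processing (epoching, artifact rejection, component scoring) is
  out of scope.
- The comparison policies for the bundled tables encode this package's
  reading of which printed cells are trustworthy; they are data
  (`KNOWN_EXCEPTIONS`), not tunable tolerances.
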