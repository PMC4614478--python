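# Methods

This note documents the simulation model, the design semantics, the
default parameters and the statistical conventions used by `numentry`,
together with the reasoning behind the choices that were genuinely open.

## The operator model

Number entry is modelled as two cognitive levels: a lower level that
executes a planned keystroke sequence and slips with some probability,
and a higher level that sometimes notices a slip immediately and issues
a repair.  Concretely:

- The planned sequence is the canonical decimal rendering of the target
  (digits and at most one point; never delete/clear).
- At each planned keystroke, each of the five error classes —
  repetition, omission, transposition, substitution, insertion — fires
  independently with its per-class probability.  At most one class takes
  effect per keystroke, chosen by first hit among the independent draws
  (at default rates a multi-class collision has probability ~4×10⁻⁶ per
  keystroke; collapsing it keeps the event bookkeeping unambiguous).
  The five draws are folded into a single uniform variate with the exact
  first-hit probabilities.
- A transposition needs a successor keystroke; at the final keystroke
  that draw falls through to error-free typing.
- Substituted keys are drawn uniformly from the digit/point alphabet
  minus the planned key; inserted keys uniformly from the full alphabet.
  No empirical confusion matrix is assumed; both alphabets are
  configurable so a keyboard-adjacency model can be plugged in.
- Each fired error is noticed with probability `1 − v`, independently,
  immediately after its realized keystrokes (an omission is noticed at
  the point of the skipped key).  Noticing is per-error, immediate and
  permanent: an unnoticed error is never caught later by the operator,
  only — possibly — by a design's own checks.
- Repairs are the canonical plans (repetition/insertion → delete;
  omission → the missing key; substitution → delete then the correct
  key; transposition → two deletes then the two keys in order) and are
  themselves error-free.  Repair keystrokes go *through the design*, so
  a repair can fail on a design with broken delete semantics; the
  operator continues as if it succeeded either way.
- On the clear-only design N a noticed error triggers CLEAR followed by
  a flawless retype of the whole plan, which ends the attempt correctly;
  hence at most one noticed error matters per entry on N, and the
  clear also erases any *earlier unnoticed* error.
- On a submission rejection, designs C/D/E/G/N start a fresh error-prone
  attempt with new error draws; design F retypes flawlessly once, making
  it the optimistic bound for design E.  Attempts are capped at 25 per
  entry; capped trials are flagged and scored as harm, never dropped (at
  default rates the cap is effectively unreachable; only design D can
  accumulate more than a couple of attempts, via its confirmation rule).

Reading and intention errors (typing the *wrong intended* number) are
out of scope, as are error-prone repair keystrokes and the operator's
choice among alternative repair strategies.

## Design semantics

The eight designs share the keystroke interface (digits, point, delete,
clear) plus a submission rule; the table in `designs.py` is normative
and the deliberately naive `reference_interpreter` is an independent
second coding that the tests compare exhaustively against the fast
implementation.

Decisions where the published descriptions left room:

- **Design A, delete on a digit-free buffer**: a no-op (nothing to
  delete; the point is untouchable by design).
- **Design B point-shift variant** (moving the point right instead of
  ignoring a second one): not implemented — a separate design.
- **Design D confirmation**: a blocked repeat-containing entry is
  accepted when the immediately following submission stores an identical
  token string.  This realises "entered twice" without livelocking on
  intended repeats such as 100.  D's re-entries are error-prone, like
  E's (the alternative — flawless re-entry — would conflate D with F).
- **Design G zero handling**: the factor-of-5 ratio is undefined when
  exactly one of entered/intended is zero, so that case is rejected;
  two zeros are accepted.  The check uses exact decimal arithmetic
  (`max ≥ 5·min`), so a ratio of exactly 5 is out of range.
- **Design N submission**: N stores every point it is given (it is a
  point-correct design with no delete key), so its buffer can
  syntactically be a two-point string.  N applies the same
  invalid-syntax rejection as C and the operator re-enters.  Besides
  being what a point-correct device that cannot *display* a two-point
  numeral would do, this choice makes a clean theorem out of N's
  advantage over C: under trial-level RNG coupling, an N-run and a C-run
  diverge only at a noticed error (where N ends correctly with zero
  harm) or at a rejection (which then fires for both), so N's per-trial
  harm never exceeds C's.  Had N blindly accepted invalid buffers, rare
  unnoticed second-point errors (probability ≈ 1.7×10⁻³·v per pointed
  target) would be scored as harm on N while C recovers by re-entry,
  breaking the dominance without reflecting any real design advantage
  of C.
- **No length or value caps** in any design: the operator can key an
  unlimited number of digits.  Digit-count limits, scrolling PIN-style
  entry, arrow keys/overwrite modes, digit-group separators, keystroke
  feedback and timing-level key bounce are all out of scope (D models
  bounce interception at the submission level only).

## Valuation and notation

Values are exact decimals throughout; harm is exact value inequality,
so `2.50` and `2.5` are the same number.  An empty buffer or a lone
point reads as 0 (common device behaviour).  A buffer with two or more
points has no numeric reading (`INVALID`); if such a buffer is ever
accepted it scores as harm.  The ISMP dose-notation rules (leading zero
required, no superfluous leading zeros, at most one point with digits
on both sides, no trailing fractional zeros) are implemented as four
switchable flags; the flag governing the fractional part also rejects a
trailing bare point (`5.`), a fractional part that adds nothing.  Every
value has exactly one ISMP-valid rendering — its canonical string — so
ISMP checking constrains notation, never the set of expressible values.

## Target distribution

The targets emulate medication-dose magnitudes: a significand of 1–3
significant digits (digit count uniform, then uniform among integers of
that length) scaled by 10^e with e uniform on {−2 … 3}, giving values
from 0.01 to 999 000 with the short, point-bearing renderings typical
of dose entry (planned lengths 1–6 keystrokes, mean ≈ 3.5, about a third
of targets containing a decimal point).  The distribution is configurable,
and an explicit plain-text target list can replace it entirely for
replay studies.  What it does *not* emulate: real dose formularies
(discrete preferred doses, units), operator familiarity effects, and
context-dependent number length; absolute risk values therefore carry
no clinical meaning — only the comparison between designs under
identical conditions does, and the ranking is insensitive to the
distribution choice in sensitivity runs with narrower grids.

## Default parameters

| parameter | default | why |
|---|---|---|
| per-class error probability | 0.002 /keystroke | total ≈ 1% per keystroke over five classes, so typical 3–5 keystroke numbers go wrong at the few-percent rates reported in empirical keying studies |
| vulnerability grid | 0.01 … 1.00, step 0.01 | 100 values; v = 0 is run separately because the risk ratio is undefined there |
| trials per grid point | 10⁴ (desk) / 10⁸ (`--full-scale`) | desk scale runs in minutes on one CPU; the binomial SE at 10⁴ is ~2×10⁻³ at the riskiest points |
| max attempts per entry | 25 | overflow probability is negligible at default rates; the cap guards degenerate configurations |

## Statistical conventions

- Risk at a grid point is a binomial mean with SE `√(r(1−r)/n)`; every
  stochastic assertion in the test suite uses a 3-SE tolerance with
  fixed seeds.
- Per-design fits are unweighted ordinary least squares of risk on
  vulnerability (an inverse-variance weighted variant is available as a
  sensitivity check).  A constant-risk fit has no explainable variance
  and reports R² = 0 by convention.
- The linearity experiment sweeps at 10⁴ trials per point and re-runs
  any design whose R² falls below the 0.9906 reference bound at 10⁵
  trials per point, where Monte Carlo noise no longer limits the fit of
  the low-risk designs (expected 1 − R² scales as 1/(n·slope)).
- Pairwise dominance of X over Y requires X's risk to be at most Y's at
  every grid vulnerability within 3 pooled SEs and strictly below
  somewhere.  A fitted-line crossing is reported only when it is
  statistically resolvable: the two lines must separate by more than 3
  pooled SEs with *opposite signs* at the two ends of the grid.  At
  finite trial counts the algebraic intersection point of two
  statistically coincident lines is noise and lands inside (0, 1] with
  substantial probability; counting only resolvable reversals makes the
  non-intersection property testable at desk scale.
- Reproducibility: every (design, v) cell and every coupled trial runs
  on its own RNG substream derived by hashing the master seed with the
  cell coordinates (SHA-256, truncated to 31 bits), so tables are
  bit-identical across runs and independent of sweep composition or
  order.  Coupled comparisons give every design the same per-trial
  stream, so the same target and the same error/noticing draws.

## What passing tests do and do not show

The differential tests (exhaustive oracle equivalence, scripted
scenarios with oracle-computed expectations) establish that the
implemented state machines mean what the design table says.  The
statistical tests establish the *structural* results — linearity,
zero/positive intercepts, the safety ordering, the closed-form check —
under the stated operator model and target distribution.  They do not
calibrate absolute error rates to any real operator population, and a
design's simulated rank is informative only to the extent that real
typing errors resemble the five modelled classes with
position-independent rates.

## Known limitations

- Uniform substitution/insertion alphabets ignore keyboard geometry.
- Noticing is all-or-nothing and immediate; real operators also catch
  errors during final visual checks, a channel deliberately absent here
  (the designs' own checks are the only late defence).
- Design D's semantics amplify entry effort for repeat-containing
  numbers; the model charges no cost for the extra keystrokes, so D's
  safety is not traded off against its efficiency.
- The clear-only design's flawless retype after a noticed error is an
  idealisation (a retype is itself typing); it is the same idealisation
  the repair-keystroke model makes everywhere, applied once per entry.
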