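# numentry

Monte Carlo safety analysis of number-entry user interfaces.

Numbers are typed into infusion pumps, calculators and spreadsheets
millions of times a day, and the interfaces that receive them differ in
subtle ways — what the delete key really removes, what happens to a
second decimal point, whether a malformed dose like `5.0` or `.5` is
accepted.  Those differences are invisible during error-free use but
decide whether an operator's *repair* of a typing slip actually works.
`numentry` makes the comparison quantitative: it simulates an error-prone
operator entering random dose-like numbers into executable models of
eight number-entry designs and measures how often each design lets a
wrong number through.

It is written for human-factors and patient-safety researchers,
interaction designers, and anyone procuring or certifying devices with
numeric keypads.

## The model

- **Vulnerability** `v`: the probability that the operator does *not*
  attempt to repair a keying error they made (`v = 0` is a perfectly
  careful operator, `v = 1` never repairs).
- **Harm**: 1 if the finally accepted number differs in exact decimal
  value from the intended number, else 0 (variants: only "out by a
  factor f" errors, or only overdoses).
- **Risk** `r`: the expectation of harm, estimated as the fraction of
  harmed entries over many simulated trials.
- **Risk ratio** `r / v`: how much risk the design adds per unit of
  operator vulnerability; it diverges as `v → 0` for designs with
  design-induced residual risk.

At each planned keystroke one of five classic typing errors can fire,
each with probability 0.002 by default: repetition, omission,
transposition of two adjacent keys, substitution, and insertion.  A
fired error is noticed with probability `1 − v`; noticed errors are
repaired with the canonical keystrokes (delete/retype — or clear and
start over on a design with no delete key), and the operator continues
as if the repair succeeded.  Whether it *did* succeed depends on the
design:

| id | short name | defining behaviour |
|----|------------|--------------------|
| A  | Broken delete & decimals | delete removes digits only, never a point; extra points silently ignored |
| B  | Fixed delete only | delete works; extra points silently ignored |
| C  | Fixed delete & decimals | digits and points treated equally; invalid syntax rejected |
| D  | Debounced | as C; entries with adjacent repeated keys must be entered twice |
| E  | ISMP | as C; rejects numbers violating ISMP dose notation (`.5`, `5.0`, `05`) |
| F  | Low bound ISMP | as E, with a flawless re-entry: E's best case |
| G  | Range check | as C; rejects values not within a factor 5 of the intended dose |
| N  | No delete (clear only) | no delete key; noticed errors are cleared and retyped |

A and B are the classic commercial defects; C and N are correct
commercial designs; D–G are safety refinements.  The simulation shows
risk is linear in vulnerability for every design, but only A and B keep
a strictly positive risk at `v = 0` — harm that no operator carefulness
can remove.

## Worked example

`python examples/compare_designs.py` sweeps designs A and C over five
vulnerability values (20 000 simulated entries per point) and prints:

```
design    v  trials    risk       se  risk_ratio  n_capped
     A 0.10   20000 0.00575 0.000535    0.057500         0
     A 0.25   20000 0.00935 0.000681    0.037400         0
     A 0.50   20000 0.01670 0.000906    0.033400         0
     A 0.75   20000 0.02410 0.001084    0.032133         0
     A 1.00   20000 0.02795 0.001166    0.027950         0
     C 0.10   20000 0.00340 0.000412    0.034000         0
     ...

design    slope  intercept  r_squared
     A 0.025676   0.003418   0.989220
     C 0.029186   0.000413   0.995497

ranking (safest first): C <= A
```

Each `risk` is the estimated probability that the accepted number is
wrong at that vulnerability, with its binomial standard error.  The OLS
fits summarise each design as a line: A's intercept (≈ 0.0034) is its
residual risk for a *perfect* operator — on A, repairing a noticed slip
near a decimal point deletes the wrong token — while C's line passes
through the origin.  A's risk ratio grows as `v` shrinks: the more
careful the operator, the larger the share of risk the design itself
contributes.

Other narrative examples: `examples/pathology_gallery.py` (deterministic
keystroke-by-keystroke replays of the classic failure modes),
`examples/closed_form_check.py` (simulated risk of the clear-only design
against its closed form), `examples/risk_figures.py` (the standard risk
and risk-ratio figures).

## Command line

```sh
numentry sweep --designs ABCDEFGN --trials 10000 --seed 1 --out sweep.csv
numentry fit --in sweep.csv
numentry compare --in sweep.csv
numentry replay --design A --keys '1.<' --target 1.5
numentry designs
```

`sweep` accepts a YAML config file (`--config`) mirroring all flags;
`--full-scale` switches to 10^8 trials per point for cluster runs.

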