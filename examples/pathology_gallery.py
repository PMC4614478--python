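"""Replay the curated keystroke pathologies through their designs.

Each scenario scripts one number entry — the intended value, the typing
errors injected at specific keystrokes, and whether the operator noticed
them — and replays it deterministically.  The table shows how the same
operator behaviour ends well or badly depending on the design.
"""

from numentry import format_keys, pathology_suite, replay_scenario

print(f"{'scenario':42s} {'design':6s} {'intended':>8s} {'final':>8s} "
      f"{'harm':>4s}  key log")
for sc in pathology_suite():
    trial = replay_scenario(sc)
    print(f"{sc.name:42s} {sc.design:6s} {sc.intended.canonical:>8s} "
          f"{str(trial.final_value):>8s} {trial.harm:>4d}  "
          f"{format_keys(trial.realized_keys)}")

# Key-log notation: digits and '.', '<' = delete, '#' = clear, '=' = submit.
# harm=1 means the accepted value differs from the intended one.  Compare
# the A/B rows with their C counterparts: identical operator keystrokes,
# different outcomes — the design alone decides whether a repair works.
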