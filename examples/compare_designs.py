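"""Sweep two number-entry designs and compare their risk.

Design A (delete only removes digits, extra decimal points silently
ignored — common in commercial calculators) is swept against design C
(digits and points treated equally) over a coarse vulnerability grid.
"""

from numentry import ErrorModel, ExperimentConfig, compare_designs, fit_all, sweep

config = ExperimentConfig(
    designs=("A", "C"),
    v_grid=(0.1, 0.25, 0.5, 0.75, 1.0),
    trials_per_point=20_000,
    operator=ErrorModel(per_class_error_prob=0.002),
    seed=1,
)

table = sweep(config)
print(table.to_string(index=False))
print()
print(fit_all(table).to_string(index=False))
print()
print(compare_designs(table).to_text())

# Each row estimates the probability (risk) that the finally accepted
# number differs from the intended one at operator vulnerability v (the
# probability of not repairing a noticed typing error).  Design A's
# intercept is positive: even a perfectly careful operator (v=0) is
# harmed, because A's delete key cannot remove decimal points, so some
# repairs corrupt the entry.  Design C's risk extrapolates to zero at
# v=0 and stays below A's everywhere.
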