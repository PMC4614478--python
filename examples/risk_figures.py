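"""Produce the standard risk and risk-ratio figures for all designs.

A coarse sweep of all eight designs, plotted two ways: risk against
vulnerability (lower lines are safer) and risk ratio r/v against
vulnerability (defective designs diverge as the operator gets more
careful).  Figures are written next to this script.
"""

from pathlib import Path

from numentry import ExperimentConfig, fit_all, sweep
from numentry.plotting import save_figures

config = ExperimentConfig(
    v_grid=tuple(round(0.1 * i, 10) for i in range(1, 11)),
    trials_per_point=10_000,
    seed=1,
)
table = sweep(config)
print(fit_all(table).to_string(index=False))

out = Path(__file__).resolve().parent
save_figures(table, out / "risk_vs_v.png", out / "risk_ratio_vs_v.png")
print(f"wrote {out/'risk_vs_v.png'} and {out/'risk_ratio_vs_v.png'}")

# In the fits, designs A and B carry positive intercepts (risk that no
# operator carefulness can remove); the other designs pass through the
# origin, and the ratio plot shows A/B's risk ratio exploding as v -> 0.
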