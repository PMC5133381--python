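"""Check whether a finding depends on a few variants, by re-estimating on
subsets.

With 17 variants: leave-one-out (17 estimates), systematic leave-two-out
(C(17,2) = 136 estimates), and 500 random subsets each omitting 30% of
the variants (round(17 x 0.3) = 5).  If the whole spread of subset
estimates stays on one side of the null, no small group of instruments
drives the conclusion.
"""

from mrsense import (
    SimulationConfig, leave_k_out, leave_one_out, orient_to_exposure,
    random_subsets, simulate_dataset,
)

data, _ = simulate_dataset(SimulationConfig(J=17, theta=0.25, seed=11))
data = orient_to_exposure(data)

for label, summary in [
    ("leave-one-out", leave_one_out(data, method="ivw")),
    ("leave-two-out", leave_k_out(data, 2, method="ivw")),
    ("random 30%-omission", random_subsets(data, 0.30, n_reps=500, seed=11, method="ivw")),
]:
    lo, hi = summary.extremes
    print(f"{label:<22} {len(summary.estimates):>4} estimates in [{lo:.3f}, {hi:.3f}]; "
          f"fraction positive = {summary.fraction_positive:.3f}")

print("\nEvery subset estimate is positive: the (true, simulated) effect of "
      "0.25 is supported by the bulk of the instruments, not a lucky few.")
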