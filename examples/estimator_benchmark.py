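"""Monte Carlo operating characteristics: why robust estimators earn
their name.

Under the causal null with directional pleiotropy on 30% of 50 variants,
the fixed-effect IVW estimate is biased and rejects the (true) null far
too often, while the weighted median - anchored to the valid majority of
the weight - stays much closer to the nominal 5% rate.  (200 replicates
here for speed; the rates stabilize with more.)
"""

from mrsense import SimulationConfig, operating_characteristics

config = SimulationConfig(J=50, theta=0.0, pleiotropy="directional",
                          invalid_fraction=0.30, pleiotropy_scale=0.1)

print(f"{'method':<18}{'rejection rate':>15}{'bias':>9}{'rmse':>9}")
for method, kwargs in [("ivw", {}), ("egger_random", {}),
                       ("weighted_median", {"n_boot": 200})]:
    oc = operating_characteristics(config, method, n_sims=200, alpha=0.05,
                                   seed=21, **kwargs)
    print(f"{oc.method:<18}{oc.rejection_rate:>15.3f}{oc.bias:>9.3f}{oc.rmse:>9.3f}")

print("\nTrue theta = 0: every rejection is a false positive.  IVW inherits "
      "the pleiotropic bias; the weighted median suppresses most of it.")
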