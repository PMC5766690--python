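"""Seeded end-to-end scenario: data-length sweep.

Runs the full simulate -> estimate -> evaluate -> infer pipeline over a
sweep of data lengths on a small network and prints the result table: the
coefficient L2 distance falls and the connectivity MCC rises as more cycles
of spikes are observed.
"""

from phasebayes.bayes import EstimatorConfig
from phasebayes.io import ScenarioConfig, run_scenario
from phasebayes.synthesize import SynthConfig

cfg = ScenarioConfig(
    synth=SynthConfig(n_units=8, k_in=3, coupling_scale=0.05),
    estimator=EstimatorConfig(),
    cycle_counts=(100, 300, 1000),
    seeds=(0,),
)
df, manifest = run_scenario(cfg, master_seed=1)
print(df[["cycles", "mean_l2", "median_l2", "mcc", "kappa_mean"]].to_string(index=False))
print(f"\nconfig hash {manifest.config_hash[:12]}..., "
      f"runtime {manifest.runtimes_s['total']:.1f} s")
print("Longer recordings sharpen the interaction estimates (smaller L2) and")
print("push the inferred connectivity toward perfect agreement (MCC -> 1).")
print("Single-seed cells vary: a draw whose frequencies cluster within the")
print("locking range partially synchronizes and recovers less well -- sweep")
print("several seeds for stable summaries.")
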