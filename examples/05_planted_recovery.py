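"""Directional recovery of a planted differential co-expression module.

Runs the full pipeline on the standard simulation scenario (30 genes, one
4-gene module correlated at 0.9 in cases and 0 in controls, 40 + 40 samples)
and scores how much of the planted module each mining direction recovers.
Takes ~half a minute.
"""

from wigamine import MiningConfig, build_network_set, top_k_patterns
from wigamine.synthetic import generate_dataset, planted_recovery_score, standard_scenario

config = standard_scenario(seed=0)
dataset = generate_dataset(config)
netset = build_network_set(dataset, tau_r=0.9)

forward = top_k_patterns(netset, config=MiningConfig(k=20, x_percent=20.0))
reverse = top_k_patterns(netset, config=MiningConfig(k=20, x_percent=20.0,
                                                     direction="reverse"))

print(f"forward (cases guide):    recovery = {planted_recovery_score(forward, config):.3f}")
print(f"reverse (controls guide): recovery = {planted_recovery_score(reverse, config):.3f}")
print("\ntop-5 forward patterns:")
for sp in forward[:5]:
    print(f"  pow={sp.pow:.4f}  edges={[f'{a}-{b}' for a, b in sp.pattern.edges]}")
print("\nMining in the case-guided direction surfaces the planted module's")
print("gene pairs; the control-guided direction finds only control-enriched")
print("chance structure and recovers (almost) none of the module.")
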