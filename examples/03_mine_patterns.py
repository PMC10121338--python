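"""Top-k discriminative pattern mining between two populations.

End-to-end run on a small planted instance: generate data, build the two
network sets, and mine the patterns whose incidence profile best separates the
case networks from the controls.
"""

from wigamine import MiningConfig, build_network_set, generate_dataset, top_k_patterns
from wigamine.synthetic import PlantedModule, SyntheticConfig, planted_recovery_score

config = SyntheticConfig(
    n_genes=20, m1=40, m2=40, seed=3,
    modules=(PlantedModule(genes=("G01", "G02", "G03", "G04"), rho1=0.9, rho2=0.0),),
)
dataset = generate_dataset(config)
netset = build_network_set(dataset, tau_r=0.9)

results = top_k_patterns(netset, config=MiningConfig(k=10, x_percent=20.0))

print("rank  pow(bits)  sup1/sup2  s_hat1/s_hat2  edges")
for i, sp in enumerate(results, 1):
    p = sp.profile
    edges = ", ".join(f"{a}-{b}" for a, b in sp.pattern.edges)
    print(f"{i:>4}  {sp.pow:9.4f}  {p.support1:>4}/{p.support2:<4} "
          f"{p.s_hat1:6.2f}/{p.s_hat2:<6.2f} {edges}")

score = planted_recovery_score(results, config)
print(f"\nplanted-pair recovery: {score:.2f}")
print("pow is the information gain the pattern's incidence-at-x% profile")
print("induces on the case/control split: patterns recurring with high match")
print("values in cases but not controls score highest, and the planted module's")
print("gene pairs dominate the top ranks.")
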