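"""One weighted association network per individual.

Generates a small two-population dataset with one planted co-expression module
(correlated only in the cases) and builds the per-sample filtered networks.
"""

from wigamine import build_network_set, generate_dataset
from wigamine.synthetic import PlantedModule, SyntheticConfig

config = SyntheticConfig(
    n_genes=12, m1=10, m2=10, seed=7,
    modules=(PlantedModule(genes=("G01", "G02", "G03"), rho1=0.9, rho2=0.0),),
)
dataset = generate_dataset(config)
netset = build_network_set(dataset, tau_r=0.9)

planted = {("G01", "G02"), ("G01", "G03"), ("G02", "G03")}
print("sample      class    edges  planted-module edges present")
for net in netset.all_networks:
    hits = sorted(e for e in net.weights if e in planted)
    print(f"{net.sample_id:<11} {net.label:<8} {len(net.weights):>5}  {hits}")

n1_hits = sum(1 for n in netset.n1 for e in n.weights if e in planted)
n2_hits = sum(1 for n in netset.n2 for e in n.weights if e in planted)
print(f"\nplanted-pair edges: {n1_hits} across case networks vs {n2_hits} across controls.")
print("The module's pairs recur across the case networks because correlated")
print("genes co-deviate sample after sample; in controls they appear only at")
print("the chance rate every unrelated pair shares.")
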