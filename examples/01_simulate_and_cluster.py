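"""Cover a modular PPI network with overlapping clusters.

Builds a small synthetic interactome with three planted functional
modules that share two proteins, runs the overlapping clustering and
compares the recovered clusters with the planted truth.
"""

import moonnet as mn
from moonnet.synthetic import ScenarioParams, generate_scenario

scenario = generate_scenario(ScenarioParams(seed=7))
net = scenario.network
print(f"network: {net.number_of_nodes()} proteins, "
      f"{net.number_of_edges()} interactions")

system = mn.ocg_cluster(net)
print(f"clusters found: {len(system)} "
      f"(sizes {sorted(len(c) for c in system.clusters)})")

multi = mn.find_multiclustered(system)
print(f"multiclustered proteins: {', '.join(multi)}")

score = mn.recovery_score(system, scenario.true_modules)
print(f"best-match Jaccard vs planted modules: {score:.2f}")
# 1.00 means every planted module is recovered exactly, including the
# shared proteins that belong to two modules at once.
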