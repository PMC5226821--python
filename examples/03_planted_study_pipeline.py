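"""Full pipeline on a simulated replicate-set study with known truth.

Plants a densely interacting 12-gene driver module in a 100-gene network,
simulates 4 replicate sets with 30% dropout and 2% spurious background
calls, runs propagation + filtering per replicate set, and pools the kept
interactions into the consensus driver network.  Recovery of planted versus
background genes summarizes how well the consensus rule suppresses
replicate noise.
"""

from m6adriver import (
    RandomizationConfig,
    build_null_model,
    generate_planted_study,
    generate_toy_ppi,
    run_study,
    sites_to_genes,
)

network = generate_toy_ppi(100, rng_seed=7)
study = generate_planted_study(
    network, module_size=12, n_rs=4, dropout=0.3, background_rate=0.02, rng_seed=3
)
model = build_null_model(network, RandomizationConfig(n_networks=20, rng_seed=11))

genesets = [sites_to_genes(sites, rs) for rs, sites in study.site_tables.items()]
result = run_study(network, genesets, model)

print("per-RS differential methylation calls:")
print(result.summary.to_string(index=False), "\n")

drivers = result.mdr_genes
module = study.module_genes
background = set(network.nodes()) - module
print(f"planted module ({len(module)}): {' '.join(sorted(module))}")
print(f"predicted drivers ({len(drivers)}): {' '.join(sorted(drivers))}")
print(f"consensus edges (present in all {study.n_rs} RSs): "
      f"{len(result.consensus.edges)}")
print(f"module recovery:     {len(drivers & module) / len(module):.2f}")
print(f"background recovery: {len(drivers & background) / len(background):.3f}")
print("\nModule genes recur across replicate sets and interact densely, so "
      "their edges survive the every-RS consensus rule; sporadic background "
      "calls do not.")
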