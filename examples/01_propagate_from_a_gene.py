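"""Propagate from one gene with Random Walk with Restart.

Builds a small scale-free interaction network, starts a walk at a single
gene with restart probability 0.5, and prints the ten most accessible other
genes.  Higher stationary probability means the walker, repeatedly pulled
back to the seed, still reaches that gene often — a proximity measure that
uses all paths, not just the shortest one.
"""

from m6adriver import (
    RWRConfig,
    build_transition_matrix,
    generate_toy_ppi,
    run_rwr,
    top_candidates,
)

network = generate_toy_ppi(100, rng_seed=7)
tm = build_transition_matrix(network)
seed = "G001"

pv = run_rwr(tm, {seed}, RWRConfig(restart_prob=0.5))
print(f"walk from {seed} (degree {network.degree(seed)}) "
      f"converged in {pv.iterations} iterations\n")
print(f"{'rank':>4}  {'gene':<6} {'probability':>11}  direct neighbor?")
for rank, (gene, prob) in enumerate(top_candidates(pv, 10), start=1):
    neighbor = "yes" if network.has_edge(seed, gene) else "no"
    print(f"{rank:>4}  {gene:<6} {prob:>11.4f}  {neighbor}")
print("\nThe seed itself retains >= 0.5 of the probability mass "
      f"(here {pv[seed]:.3f}); candidates split the rest by network proximity.")
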