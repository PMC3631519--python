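"""Pairwise relatedness: from IBS counts to degree-of-relatedness calls.

Simulates relative pairs of each degree by gene-dropping and shows the
method-of-moments genome-share estimates next to their pedigree
expectations (1/2, 1/4, 1/8, 1/16, 0).
"""

from forensnp import sim
from forensnp.kinship import kinship_pair

config = sim.SimConfig(
    n_populations=2, n_autosomal=20_000, n_x=100, drift=(0.05, 0.05), seed=5
)
ref = sim.simulate_reference_panel(config, n_per_pop=25)
freqs = ref.freq_auto[0]

print(f"{'relationship':28s} {'expected':>9s} {'pi_hat':>7s} {'degree':>10s}")
for offset, (degree, expected) in enumerate(
    [(1, 0.5), (2, 0.25), (3, 0.125), (4, 0.0625), ("unrelated", 0.0)]
):
    pair, ta, tb = sim.simulate_relative_pair(ref, "POP1", degree, seed=60 + offset)
    r = kinship_pair(pair, *pair.sample_ids, freqs=freqs)
    name = sim.DEGREE_RELATIONSHIPS.get(degree, "unrelated")
    print(f"{name:28s} {expected:9.4f} {r.pi_hat:7.4f} {r.degree:>10s}")
# pi_hat tracks the pedigree expectation; the degree call is the bin whose
# midpoint boundaries (0.375 / 0.1875 / 0.09375 / 0.046875) contain it.
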