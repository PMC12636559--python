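"""Build the reference hourglass connectome and query its connectivity.

Prints the synapse-weighted connectivity fractions the synthetic circuit is
constructed to reproduce, plus the ascending-neuron classification: FDA-I
cell types synapse directly onto PAM dopaminergic neurons, FDA-II reach them
through one intermediate layer.
"""

from foxcircuit import (
    GeneratorConfig,
    by_cell_type,
    by_population,
    classify_fda,
    generate_reference,
    input_fraction,
    output_fraction,
    pair_count,
)

graph, truth = generate_reference(GeneratorConfig())
print(f"reference connectome: {graph.n_neurons} neurons, "
      f"{graph.n_edges} aggregated connections")

fox = by_cell_type("fox")
fda1, fda2 = classify_fda(graph, fox.resolve(graph),
                          by_population("PAM").resolve(graph))

print(f"\nFdg -> fox input share:       "
      f"{input_fraction(graph, fox, by_cell_type('Fdg')):.1f} %")
print(f"fox -> FDA-I output share:    "
      f"{output_fraction(graph, fox, fda1):.1f} %")
print(f"fox -> FDA-II output share:   "
      f"{output_fraction(graph, fox, fda2):.1f} %")
print(f"CB0233 share of fox output:   "
      f"{output_fraction(graph, fox, by_cell_type('CB0233')):.1f} %")
print(f"CB0233 share of fox->FDA:     "
      f"{output_fraction(graph, fox, by_cell_type('CB0233'), within=fda1 | fda2):.1f} %")
print(f"fox share of DSKMP1B SEZ in:  "
      f"{input_fraction(graph, by_cell_type('DSKMP1B'), fox, region_filter='SEZ'):.1f} %")
print(f"\nascending pairs downstream of fox: "
      f"{pair_count(graph, fda1 | fda2)} "
      f"({pair_count(graph, fda1)} direct onto PAM, "
      f"{pair_count(graph, fda2)} one synapse upstream)")
print("\nEach percentage is (synapses from source onto target) / (all "
      "synapses onto or out of the reference population), x 100.")
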