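"""Score a protein-RNA complex model with the graph-transformer network.

Builds a small synthetic complex, featurizes it into a residue graph and
runs a (randomly initialized, untrained) network, printing the raw and
combined quality predictions. With trained checkpoints the same call ranks
real docking decoys; untrained outputs just demonstrate the score surface.
"""

from rnpqa import ModelConfig, combined_scores, featurize, init_model, make_toy_complex, predict

complex_ = make_toy_complex(n_protein_res=12, n_rna_res=8, seed=1)
graph = featurize(complex_)
print(f"graph: {graph.n_nodes} residues, {len(graph.edges)} edges, "
      f"{int(graph.interface_mask.sum())} interface residues, "
      f"interfaces {graph.interfaces}")

config = ModelConfig(seed=0)
params = init_model(config)
out = predict(graph, params, config)
scores = combined_scores(out)

print("raw fold predictions  (bb-lDDT, GDT-TS, GDT-HA):", out.fold.round(3))
print("raw iface predictions (iLDDT, IPS, ICS):        ", out.iface.round(3))
for pair, p in out.per_interface:
    print(f"raw per-interface {pair} (IPS, ICS):           ", p.round(3))
print()
for name, value in scores.as_dict().items():
    print(f"{name:>16s} = {value:.3f}")
print("\nEach combined score averages the raw sigmoid outputs named above;")
print("all live in (0,1), higher meaning better predicted quality.")
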