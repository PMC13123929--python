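"""Spectral-wavelet embeddings on a toy weighted network.

Shows the core mechanics: expression -> edge weights -> heat-kernel wavelet
embeddings -> joint PCA distances. Two conditions differ only at one gene,
and the distance ranking localises the perturbation.
"""

import pandas as pd

import diffembed as de

edges = pd.DataFrame({
    "protein1": ["A", "A", "B", "C", "D", "E"],
    "protein2": ["B", "C", "C", "D", "E", "F"],
    "combined_score": [900, 800, 700, 600, 500, 450],
})
base = de.load_string_edges(edges, min_confidence=0.4)

control = de.ExpressionProfile(
    values=pd.Series({"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0, "E": 1.0, "F": 0.5}),
    condition_label="control")
# disease: gene D collapses to the zero-count floor, log2(0.125) = -3
disease_values = control.values.copy()
disease_values["D"] = -3.0
disease = de.ExpressionProfile(values=disease_values, condition_label="disease")

net_control = de.build_weighted_network(base, control)
net_disease = de.build_weighted_network(base, disease)
print("edge weights rescaled to [0, 2]; control range:",
      round(net_control.weight_array().min(), 3), "-",
      round(net_control.weight_array().max(), 3))

emb_disease, emb_control = de.embed_pair(net_disease, net_control)
print(f"embedding dimension: {emb_control.n_dims} "
      "(2 diffusion scales x 25 char.-function points x Re/Im)")

table = de.node_distances(emb_disease, emb_control)
print(f"explained variance of PC1+PC2: {table.explained_variance:.3f}")
print(table.distances.sort_values(ascending=False).round(4).to_string())
# The perturbed gene D tops the distance ranking: embedding distance
# localises where the network context changed.
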