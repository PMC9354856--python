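"""Read-across in PCA space: scores, influential genes, neighbors.

Fits a centered PCA to a predicted expression matrix, ranks the genes of the
first and fourth loading quadrants by loading length (the Euclidean norm of
their PC1/PC2 loadings), projects held-out substances into the training
geometry, and retrieves the nearest biological neighbors of one external
substance in the (PC1, PC2) plane.
"""

from raidkit import (
    SimulationConfig,
    biosimilar_neighbors,
    fit_pca,
    generate,
    project,
    quadrant_top_genes,
)
import pandas as pd

sim = generate(SimulationConfig(n_substances=50, n_test_substances=5, seed=31))
train = sim.truth.invivo_log2.loc[sim.train_substances]
external = sim.truth.invivo_log2.loc[sim.test_substances]

pca = fit_pca(train)
ratio = pca.explained_variance_ratio
print(f"PC1 {ratio[0]:.1%} and PC2 {ratio[1]:.1%} of variance")

for q in (1, 4):
    ranking = quadrant_top_genes(pca, quadrant=q, k=3).entries
    genes = ", ".join(
        f"{r.gene} (len {r.loading_length:.3f})" for r in ranking.itertuples()
    )
    print(f"quadrant {q} top genes: {genes}")

scores = pca.scores[["PC1", "PC2"]]
ext_scores = project(pca, external)[["PC1", "PC2"]]
all_scores = pd.concat([scores, ext_scores])

query = sim.test_substances[0]
print(f"\nnearest neighbors of external substance {query}:")
print(biosimilar_neighbors(all_scores, query, k=3).to_string(index=False))

# Neighbors close in the score plane respond similarly across the gene panel:
# read-across borrows their in vivo evidence for the query substance.
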