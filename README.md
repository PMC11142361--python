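# cocost — contrastive feature representations for paired spatial transcriptomics

Variance-maximizing reductions (PCA, NMF, factor models) applied to a spatial
transcriptomics slice latch onto its dominant, high-variance structure — in a
precancer setting, typically the normal-tissue spatial pattern. Small regions
of genuine interest (early hyperplastic or adenomatous foci) carry far less
variance and are easily masked. `cocost` addresses this by *contrasting* two
slices: a **background** slice carrying only the dominant shared structure,
and a **target** slice that additionally contains the structures of interest.

## The model

Let `X_b` (genes × background spots) and `X_t` (genes × target spots) be
standardized expression matrices. For each slice a kNN graph with heat-kernel
weights `S_ij = exp(-||p_i - p_j||² / t)` is built on either the expression
profiles or the 2-D spot coordinates, and its symmetric normalized Laplacian
`L̄ = D^{-1/2}(D - S)D^{-1/2}` defines a smoothing filter `H = I - μ L̄`
(μ ∈ [0, 1]). The projection `W` (genes × p, orthonormal columns) maximizes

    tr(Wᵀ X_t H_t X_tᵀ W) − η · tr(Wᵀ X_b H_b X_bᵀ W),   WᵀW = I,

i.e. graph-smoothed variance in the target minus η times the same quantity
in the background. The solution is the top eigenvectors of the symmetric
contrast matrix `M = X_t H_t X_tᵀ − η X_b H_b X_bᵀ`; spot embeddings are
`Z = Wᵀ X`. With `μ₁ = μ₂ = 0` this is exactly contrastive PCA; with
`η = 0` it is a graph-smoothed PCA of the target alone. A kernelized
variant solves the analogous generalized eigenproblem
`(K_ct H_t K_tc − η K_cb H_b K_bc) A = Λ (K_cc + ρI) A` in an RKHS.
New slices are embedded by reusing the learned `W` (or kernel coefficients
`A`), so one background/target fit transfers to a whole series of samples.

## Worked example

A built-in simulator plants a dominant shared spatial band (40-gene program,
variance scale 1) in both slices and a 25-spot "hotspot" (20-gene program at
one tenth of the band's variance, genes `gene_0040`–`gene_0059`) in the
target only:

```python
import numpy as np
import cocost
from cocost.synthetic import hotspot_labels

config = cocost.default_scenario(seed=0)
background, target, _, labels_t = cocost.generate_pair(config)
b, t = cocost.preprocess_pair(background, target, cocost.PreprocessConfig(n_hvg=150))

model = cocost.fit(b, t, eta=2.0, mu1=0.5, mu2=0.5, k=4, p=5, graph_mode="spatial")
print("eigenvalues:", np.round(model.eigenvalues, 1))
print("top genes (CC1):", [(g, round(w, 3), s) for g, w, s in cocost.top_genes(model, 1, top_k=5)])

Z = cocost.transform(model, t)
truth = hotspot_labels(config, labels_t)
print("hotspot recovery:", cocost.evaluate_recovery(Z, truth, n_clusters=2, seed=0))
```

prints

```
eigenvalues: [370.7  70.3  60.1  54.7  54.1]
top genes (CC1): [('gene_0051', 0.208, '+'), ('gene_0053', 0.199, '+'), ('gene_0045', 0.19, '+'), ('gene_0052', 0.186, '+'), ('gene_0042', 0.177, '+')]
hotspot recovery: {'ari': 0.978, 'nmi': 0.947}
```

The leading contrastive component loads on the planted hotspot program and
2-means clustering of the embedding recovers the 25 hotspot spots almost
perfectly (adjusted Rand index 0.98). A target-only PCA baseline
(`eta=0, mu=0`) on the same data scores ARI ≈ 0: its leading components
track the dominant band, not the hotspot.

The same pipeline is available from the shell:

```
cocost synth --out data/ --seed 0
cocost fit --config config.yaml --out run/
cocost transform --model-dir run/model --matrix new_slice.tsv --coords new_coords.tsv --out Z_new.tsv
cocost cluster --embedding run/Zt.tsv --n-clusters 2 --out domains.tsv
```

Input formats: 10x-style MTX triplets (matrix + features/genes + barcodes)
or delimited text matrices, plus a `spot_id, x, y` coordinate table (Visium
`tissue_positions` columns are recognized).

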