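"""Cluster synthetic spot/stripe/labyrinth fields by barcode distance.

Thirty seeded fields (ten per class) are summarised by four barcodes each
and clustered under the composite d1 metric with silhouette-based
selection of linkage and cluster count.
"""

from sklearn.metrics import adjusted_rand_score

from turingtda import (
    BarcodeSet,
    PatternKind,
    PatternSpec,
    build_grid,
    clean_barcode,
    compute_barcodes,
    distance_matrix,
    make_pattern,
    select_clustering,
    star_filtration,
    triangulate_grid,
)

grid = build_grid(20.0, 20.0, 0.5)
cx = triangulate_grid(grid)

classes = {
    "spots": lambda s: PatternSpec(PatternKind.SPOTS, 4, 4, noise_sd=0.05, seed=s),
    "stripes": lambda s: PatternSpec(PatternKind.STRIPES, 6, noise_sd=0.05, seed=s),
    "labyrinth": lambda s: PatternSpec(PatternKind.LABYRINTH, 5, 1, noise_sd=0.05, seed=s),
}
nodes, truth = [], []
for label, spec_of in classes.items():
    for seed in range(10):
        field, _ = make_pattern(spec_of(seed), grid)
        lo = compute_barcodes(star_filtration(field, cx, "lower"))
        up = compute_barcodes(star_filtration(field, cx, "upper"))
        nodes.append(
            BarcodeSet(
                node_id=len(nodes),
                b0u=clean_barcode(lo[0], 5),
                b1u=lo[1],
                b0v=clean_barcode(up[0], 5),
                b1v=clean_barcode(up[1], 5),
            )
        )
        truth.append(label)

D = distance_matrix(nodes, variant="d1")
result = select_clustering(D, k_range=range(2, 13))
ari = adjusted_rand_score(truth, result.labels)
print(f"selected         k = {result.k} clusters, linkage = {result.linkage}")
print(f"silhouette       {result.silhouette:.3f}  (1 = perfectly separated)")
print(f"adjusted Rand    {ari:.3f}  vs the planted classes (1 = exact recovery)")
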