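"""Golgi fragmentation scoring: intact vs. fragmented populations.

Renders single-cell images with either one large Golgi object (intact
ribbon) or many small ones (dispersed mini-stacks), scores each cell as
the fraction of Golgi staining in objects larger than 4.11 µm²
normalised by the cell's marker expression, and compares populations
with Welch's t-test.  Also demonstrates masked Pearson colocalization
and the per-cell total-intensity QC.
"""

import numpy as np

from vesitrack import (GolgiObjectSpec, ImageSimParams, compare_conditions,
                       golgi_fragmentation_score, pearson_colocalization,
                       render_cell_image, segment_channel,
                       total_cell_intensity)

CELL = np.array([[1, 1], [24, 1], [24, 24], [1, 24]], dtype=float)
rng = np.random.default_rng(0)


def score_cell(objects, seed):
    image = render_cell_image(ImageSimParams(
        image_shape=(140, 140), pixel_size=0.2, cell_polygons=[CELL],
        golgi_objects=objects,
        marker_mean_intensity=float(rng.normal(100, 10)),
        background=5.0, noise_sd=2.0, seed=seed))
    labels = segment_channel(image.golgi, 0.2, method="fixed",
                             threshold=40.0, min_object_area=0.2)
    scores, _ = golgi_fragmentation_score(image.golgi, labels,
                                          image.cell_labels, image.marker,
                                          area_threshold=4.11)
    return scores[0], image


intact, fragmented = [], []
grid = [(5.0 + 4.5 * (i % 4), 5.0 + 4.5 * (i // 4)) for i in range(10)]
for i in range(30):
    s, img = score_cell([GolgiObjectSpec((13.0, 13.0), 20.0, 100.0)], seed=i)
    intact.append(s)
    s, _ = score_cell([GolgiObjectSpec(c, 1.0, 100.0) for c in grid],
                      seed=1000 + i)
    fragmented.append(s)

cmp = compare_conditions(intact, fragmented)
print(f"intact:     normalized score {cmp.mean_a:.5f} ± {cmp.se_a:.5f} (n={cmp.n_a})")
print(f"fragmented: normalized score {cmp.mean_b:.5f} ± {cmp.se_b:.5f} (n={cmp.n_b})")
print(f"Welch t = {cmp.statistic:.1f}, p = {cmp.pvalue:.2e}")

coloc = pearson_colocalization(img.golgi, img.marker, img.cell_labels)
totals = total_cell_intensity(img.marker, img.cell_labels)
print(f"\nGolgi-vs-marker Pearson r in the last cell: {coloc['pooled_r']:.3f}")
print(f"total marker intensity of that cell: {totals[1]:.0f} AU")

print("""
An intact ribbon concentrates its staining in one object above the
4.11 µm² cutoff (score near 1/marker); dispersed mini-stacks fall
below it (score near 0), so the two populations separate sharply.
The Pearson r is low because Golgi staining is punctate while the
marker fills the whole cell; the total intensity is the
expression-matching QC used before comparing conditions.""")
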