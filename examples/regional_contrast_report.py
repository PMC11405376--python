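"""Full regional pipeline: UTJ-like vs AIJ-like phantom suites.

Runs the end-to-end chain (phantom -> segmentation -> fold caliper ->
fractal statistics) for two synthetic regions built to the published
qualitative anatomy — the utero-tubal junction (UTJ) with few small
folds, the ampullary-isthmic junction (AIJ) with many large ones — and
prints the contrast table.  Expected directions: AIJ folds larger, AIJ
fractal dimension higher, AIJ lacunarity lower.
"""

from oviscan.pipeline import PipelineConfig, compare_regions, run_region_analysis

utj = run_region_analysis(PipelineConfig(
    region="UTJ", n_slices=4, seed=1,
    fold_phantom=dict(n_folds=4, fold_length_px=(20.0, 70.0),
                      fold_width_px=(10.0, 26.0), lumen_radius_px=180.0,
                      image_size_px=(576, 576)),
))
aij = run_region_analysis(PipelineConfig(
    region="AIJ", n_slices=4, seed=2,
    fold_phantom=dict(n_folds=9, fold_length_px=(60.0, 130.0),
                      fold_width_px=(14.0, 36.0), lumen_radius_px=230.0,
                      image_size_px=(672, 672)),
))

for r in (utj, aij):
    print(f"{r.region}: {r.fold_summary.count} folds over 4 slices, "
          f"length {r.fold_summary.length_min_um:.0f}-{r.fold_summary.length_max_um:.0f} um, "
          f"fd median {r.fd_median:.3f}, lacunarity median {r.lacunarity_median:.2f}")

print("\ncontrast (AIJ - UTJ):")
print(compare_regions(utj, aij).to_string(index=False))
print("\npositive fold sizes + fd, negative lacunarity reproduce the "
      "published regional pattern at phantom scale.")
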