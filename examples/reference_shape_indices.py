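"""Recompute published oviduct shape indices from their printed V, S, h.

The reference table carries the published (volume, surface, height)
triples for the external (organ solid) and internal (lumen) structures of
the swine oviduct UTJ and AIJ segments.  Applying F = S·h/V to each triple
reproduces the published shape indices; the lumen ("internal") always
scores far higher than the organ solid, because the folded lumen packs
much more surface per unit volume.
"""

from oviscan.reference_data import reference_shape_table
from oviscan.shape3d import round_half_up, shape_factor

df = reference_shape_table()
print(f"{'region':<6} {'structure':<9} {'phase':<16} {'ov':>2} "
      f"{'F recomputed':>13} {'F published':>12}")
for _, row in df.iterrows():
    res = shape_factor(row.surface_mm2, row.volume_mm3, row.height_mm)
    print(f"{row.region:<6} {row.structure:<9} {row.phase:<16} {row.oviduct:>2} "
          f"{round_half_up(res.shape_index):>13.2f} {row.shape_index_printed:>12.2f}")

ext = df[df.structure == "external"]
lum = df[df.structure == "internal"]
print(f"\nmedian published F: external {ext.shape_index_printed.median():.1f}, "
      f"internal {lum.shape_index_printed.median():.1f} "
      "(the lumen's folded surface dominates its small volume)")
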