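"""Published reference morphometry for swine oviduct segments.

Printed (volume, surface, height) triples and the shape indices reported
with them, for the external (organ solid) and internal (lumen) structures
of the utero-tubal junction (UTJ) and ampullary-isthmic junction (AIJ),
across four estrous-cycle phases and two oviducts per phase.  Height is
the constant 4.46 mm segment length used in that study design.

These values serve as **inputs** to :func:`oviscan.shape3d.shape_factor`
when reproducing the reference shape indices, and as an internal
consistency check: most printed shape-index cells recompute exactly at two
decimals from the printed (V, S, h); a handful carry printed-rounding
residue of up to ≈0.1 (the upstream unrounded values were evidently not
the printed ones), which :func:`reference_shape_table` exposes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_HEIGHT_MM", "reference_shape_table"]

REFERENCE_HEIGHT_MM = 4.46

_PHASES = ("late_follicular", "early_follicular", "late_luteal", "early_luteal")

# region, structure → per phase, per oviduct: (V mm³, S mm², printed F, printed F/h)
_ROWS = {
    ("UTJ", "external"): [
        (66.31, 234.11, 15.75, 3.53), (127.71, 353.68, 12.35, 2.77),
        (31.53, 124.53, 17.62, 3.95), (26.64, 109.56, 18.34, 4.11),
        (41.55, 170.13, 18.26, 4.09), (43.64, 130.69, 13.36, 2.99),
        (84.22, 268.53, 14.22, 3.19), (39.80, 143.59, 16.09, 3.61),
    ],
    ("UTJ", "internal"): [
        (3.95, 77.88, 87.94, 19.72), (3.2, 50.2, 69.97, 15.69),
        (0.52, 13.83, 118.62, 26.60), (0.80, 16.31, 90.93, 20.39),
        (1.66, 30.20, 81.14, 18.19), (1.58, 23.92, 67.52, 15.14),
        (7.78, 106.27, 60.92, 13.66), (2.87, 30.19, 46.92, 10.52),
    ],
    ("AIJ", "external"): [
        (40.79, 226.97, 24.82, 5.56), (44.0, 225.73, 22.88, 5.13),
        (23.6, 234.99, 44.41, 9.96), (26.51, 286.61, 48.21, 10.81),
        (29.83, 155.14, 23.20, 5.20), (23.79, 84.67, 15.87, 3.56),
        (35.10, 166.89, 21.21, 4.75), (48.41, 323.40, 29.79, 6.68),
    ],
    ("AIJ", "internal"): [
        (4.87, 66.76, 61.15, 13.71), (4.32, 73.22, 75.59, 16.95),
        (6.36, 103.86, 72.83, 16.33), (5.88, 141.18, 107.16, 24.03),
        (1.99, 41.52, 92.96, 20.84), (0.40, 8.96, 99.90, 22.40),
        (0.81, 18.91, 104.12, 23.35), (8.34, 195.45, 104.56, 23.44),
    ],
}


def reference_shape_table() -> pd.DataFrame:
    """The 32 published (V, S, h) triples with their printed shape indices.

    Columns: region, structure, phase, oviduct, volume_mm3, surface_mm2,
    height_mm, shape_index_printed, shape_index_per_mm_printed.
    """
    records = []
    for (region, structure), cells in _ROWS.items():
        for idx, (v, s, f, f_per_mm) in enumerate(cells):
            records.append(
                {
                    "region": region,
                    "structure": structure,
                    "phase": _PHASES[idx // 2],
                    "oviduct": idx % 2 + 1,
                    "volume_mm3": v,
                    "surface_mm2": s,
                    "height_mm": REFERENCE_HEIGHT_MM,
                    "shape_index_printed": f,
                    "shape_index_per_mm_printed": f_per_mm,
                }
            )
    return pd.DataFrame.from_records(records)
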