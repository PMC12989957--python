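"""Tessellate a tissue mask into tiles and apply the exclusion rules.

Builds a random low-magnification tissue/pen mask, lays the 20x tile grid
over it, and filters out tiles with under 5% tissue or any pen marking.
"""

import spitzmil as sm

mask = sm.make_synthetic_mask(320, 240, n_blobs=4, pen_strokes=2, seed=7)
grid = sm.tessellate(mask, tile_size_20x=224, scale=16)  # 14-px footprints
filtered = sm.filter_tiles(grid, min_tissue=0.05)

t = filtered.tiles
print(f"grid: {t['col'].max() + 1} x {t['row'].max() + 1} tiles ({len(t)} total)")
print(f"kept {filtered.n_kept}, excluded {filtered.n_excluded} "
      f"({(t['tissue_fraction'] < 0.05).sum()} below 5% tissue, "
      f"{t['pen_overlap'].sum()} touching pen)")
# Kept tiles are the ones whose features would enter a case's bag.
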