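"""Tiny TIL-map builders shared by io and feature tests."""

import numpy as np

from tilscope.tilquant import PatchGrid, PatchGridEntry, TILMap


def small_til_map():
    entries = []
    L, T = [], []
    rng = np.random.default_rng(0)
    for gr in range(3):
        for gc in range(4):
            valid = (gr, gc) != (2, 3)
            entries.append(
                PatchGridEntry(gr, gc, (gr * 200, gc * 200), valid,
                               0.9 if not valid else 0.1)
            )
            t = int(rng.integers(10000, 40000))
            T.append(t if valid else 0)
            L.append(int(t * rng.random() * 0.3) if valid else 0)
    grid = PatchGrid(patch_size=200, entries=tuple(entries), shape=(3, 4))
    return TILMap(grid=grid, L=np.array(L), T=np.array(T),
                  stitched_mask=np.zeros((600, 800), bool))
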