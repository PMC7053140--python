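"""Fast restyling from the cached plot state — no BAM is reopened.

Renders a heat map, deletes every source BAM, then lowers the color-scale
maximum via adjust(): the figure is redrawn purely from the cached coverage
matrix, which is useful when iterating on plots of loci with exceptionally
high read coverage.
"""

import os
import tempfile

import numpy as np

from cellpile import TrackSpec, adjust, render
from cellpile.simulate import ScenarioSpec, make_scenario

workdir = tempfile.mkdtemp(prefix="cellpile_example_")
spec = ScenarioSpec(kind="uniform", n_cells=6, seed=2, depth=300)
scn = make_scenario(spec, workdir)
sources = [(c, p, "bam") for c, p in
           zip(scn.ground_truth.cell_id, scn.bam_paths)]

state = render([TrackSpec("sc_heatmap", sources=sources)], spec.region,
               out=f"{workdir}/auto_scale.png", n_bins=150)
cached = state.matrices[0].matrix.copy()

for p in scn.bam_paths:  # sources gone: only the cache remains
    os.remove(p)
    os.remove(p + ".bai")

new_state = adjust(state, out=f"{workdir}/vmax_1.png", vmax=1.0)
print(f"restyled after deleting sources: {workdir}/vmax_1.png")
print("cached matrix bit-identical:",
      np.array_equal(new_state.matrices[0].matrix, cached))
print(f"values above vmax=1.0 now saturating: {(cached > 1.0).sum()} bins")
# adjust() only remaps colors; the coverage values themselves are untouched.
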