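"""Track rendering, color scaling, lane packing, and cached adjustment."""

import os

import numpy as np
import pytest

from cellpile import (
    GenomicRegion,
    RequiresFullRender,
    TrackSpec,
    adjust,
    build_coverage_matrix,
    color_scale,
    load_state,
    render,
    save_state,
)
from cellpile.genome import GeneModel
from cellpile.viz import (
    assign_lanes,
    draw_figure,
    render_gene_track,
    resolve_vmax,
)

from conftest import scenario_sources
from _oracles import first_fit_lanes_oracle


class TestColorScale:
    def test_all_zero_auto_fallback(self):
        vals = np.zeros((4, 5))
        assert resolve_vmax(vals, "auto") == 1.0
        colors = color_scale(vals, "auto")
        assert (colors == colors[0, 0]).all()  # uniform zero-color

    def test_explicit_vmax_at_max_no_clamp(self, rng):
        vals = rng.random((6, 6)) * 7
        top = float(vals.max())
        mapped = color_scale(vals, vmax=top)
        # the maximum maps to the top color; nothing maps beyond it
        import matplotlib
        cmap = matplotlib.colormaps["viridis"]
        np.testing.assert_allclose(
            mapped[np.unravel_index(vals.argmax(), vals.shape)], cmap(1.0))

    def test_values_above_vmax_saturate(self):
        vals = np.array([[0.0, 2.0, 10.0]])
        mapped = color_scale(vals, vmax=2.0)
        np.testing.assert_allclose(mapped[0, 1], mapped[0, 2])

    def test_auto_quantile_tames_outlier(self, rng):
        vals = np.concatenate([rng.random(199) * 10, [1000.0]])
        v = resolve_vmax(vals, "auto", q=0.99)
        assert v == pytest.approx(np.quantile(vals[vals > 0], 0.99))
        assert v < 50  # far below the outlier: it will saturate

    def test_nonpositive_vmax_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            resolve_vmax(np.ones(3), vmax=0.0)


class TestGeneTrackLayout:
    def mk(self, spans):
        return [
            GeneModel("g", f"t{i}", "+",
                      exons=(GenomicRegion("chr1", s, e),))
            for i, (s, e) in enumerate(spans)
        ]

    def test_two_exon_transcript_commands(self):
        m = GeneModel("g", "t", "+", exons=(
            GenomicRegion("chr1", 10, 20), GenomicRegion("chr1", 40, 50)))
        cmds = render_gene_track([m], GenomicRegion("chr1", 0, 100))
        kinds = [c["kind"] for c in cmds]
        assert kinds.count("exon") == 2 and kinds.count("intron") == 1
        assert {c["lane"] for c in cmds} == {0}

    def test_overlapping_transcripts_two_lanes(self):
        models = self.mk([(0, 50), (25, 80)])
        assert assign_lanes(models) == [0, 1]

    def test_first_fit_matches_oracle(self):
        spans = [(0, 30), (10, 50), (20, 60), (35, 70), (55, 90)]
        assert assign_lanes(self.mk(spans)) == first_fit_lanes_oracle(spans)

    def test_random_first_fit_sweep(self, rng):
        for _ in range(30):
            starts = rng.integers(0, 500, size=8)
            spans = [(int(s), int(s) + int(rng.integers(10, 200)))
                     for s in starts]
            assert assign_lanes(self.mk(spans)) == first_fit_lanes_oracle(spans)

    def test_outside_region_excluded(self):
        models = self.mk([(0, 10), (500, 600)])
        cmds = render_gene_track(models, GenomicRegion("chr1", 0, 100))
        assert {c["transcript_id"] for c in cmds} == {"t0"}


def _tracks_for(result):
    sources, groups = scenario_sources(result)
    return [
        TrackSpec("sc_heatmap", sources=sources, groups=groups),
        TrackSpec("sc_mean", sources=sources, groups=groups),
        TrackSpec("bed", path=result.bed_path),
        TrackSpec("gene", path=result.gtf_path),
    ]


class TestRender:
    def test_empty_gene_track_renders(self, tmp_path, region):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        out = str(tmp_path / "fig.png")
        render([TrackSpec("gene", path=str(gtf))], region, out=out)
        assert os.path.getsize(out) > 0

    def test_fixture_scenario_caches_match_direct_coverage(
            self, tmp_path, bimodal_scenario):
        region = bimodal_scenario.spec.region
        out = str(tmp_path / "fig.png")
        state = render(_tracks_for(bimodal_scenario), region, out=out, n_bins=80)
        assert os.path.exists(out)
        sources, groups = scenario_sources(bimodal_scenario)
        direct = build_coverage_matrix(sources, region, 80, groups=groups)
        np.testing.assert_array_equal(state.matrices[0].matrix, direct.matrix)
        # matrix cached in input row order; permutation kept separately
        assert state.matrices[0].cell_ids == direct.cell_ids
        assert sorted(state.ordering.permutation) == list(range(8))

    def test_all_zero_heatmap_defined_scale(self, tmp_path, region):
        from cellpile.simulate import make_bam
        p = str(tmp_path / "z.bam")
        make_bam(p, [], chrom=region.chrom, chrom_len=region.end + 100)
        sources = [(f"c{i}", p, "bam") for i in range(3)]
        out = str(tmp_path / "zero.png")
        state = render([TrackSpec("sc_heatmap", sources=sources)], region,
                       out=out, n_bins=20, method="none")
        assert os.path.getsize(out) > 0
        assert resolve_vmax(state.matrices[0].matrix, "auto") == 1.0

    def test_all_tracks_share_x_span(self, bimodal_scenario):
        region = bimodal_scenario.spec.region
        state = render(_tracks_for(bimodal_scenario), region, n_bins=50)
        fig = draw_figure(state)
        main_axes = [ax for ax in fig.axes if ax.get_label().endswith("_main")]
        assert len(main_axes) == 4
        for ax in main_axes:
            assert ax.get_xlim() == (region.start, region.end)

    def test_heatmap_rows_follow_permutation(self, bimodal_scenario):
        region = bimodal_scenario.spec.region
        state = render(_tracks_for(bimodal_scenario), region, n_bins=50)
        fig = draw_figure(state)
        heat_ax = [ax for ax in fig.axes if ax.get_label() == "track0_main"][0]
        shown = heat_ax.images[0].get_array().data
        expected = state.matrices[0].matrix[state.ordering.permutation]
        np.testing.assert_array_equal(shown, expected)
        # group color key follows the permuted group labels
        key_ax = [ax for ax in fig.axes if ax.get_label() == "track0_key"][0]
        key = key_ax.images[0].get_array().data
        groups = state.matrices[0].groups
        permuted = [groups[i] for i in state.ordering.permutation]
        changes = sum(a != b for a, b in zip(permuted, permuted[1:]))
        key_changes = sum(
            not np.allclose(key[i, 0], key[i + 1, 0]) for i in range(len(key) - 1))
        assert key_changes == changes

    def test_no_tracks_rejected(self, region):
        with pytest.raises(ValueError, match="at least one track"):
            render([], region)


class TestAdjust:
    def test_idempotent_restyle_identical_output(self, tmp_path, bimodal_scenario):
        region = bimodal_scenario.spec.region
        out1 = str(tmp_path / "a.png")
        state = render(_tracks_for(bimodal_scenario), region, out=out1, n_bins=40)
        out2 = str(tmp_path / "b.png")
        adjust(state, out=out2)
        with open(out1, "rb") as f1, open(out2, "rb") as f2:
            assert f1.read() == f2.read()

    def test_vmax_override_saturates_cache_untouched(self, tmp_path,
                                                     bimodal_scenario):
        region = bimodal_scenario.spec.region
        state = render(_tracks_for(bimodal_scenario), region, n_bins=40)
        before = state.matrices[0].matrix.copy()
        new = adjust(state, out=str(tmp_path / "v.png"), vmax=0.5)
        np.testing.assert_array_equal(new.matrices[0].matrix, before)
        fig = draw_figure(new)
        heat_ax = [ax for ax in fig.axes if ax.get_label() == "track0_main"][0]
        assert heat_ax.images[0].get_clim() == (0.0, 0.5)

    def test_adjust_after_sources_deleted(self, tmp_path, bimodal_scenario):
        """The cache makes restyling independent of the source files."""
        region = bimodal_scenario.spec.region
        state = render(_tracks_for(bimodal_scenario), region, n_bins=40)
        cached = state.matrices[0].matrix.copy()
        for p in bimodal_scenario.bam_paths:
            os.remove(p)
            os.remove(p + ".bai")
        out = str(tmp_path / "after.png")
        new = adjust(state, out=out, vmax=3.0, reorder="group")
        assert os.path.getsize(out) > 0
        np.testing.assert_array_equal(new.matrices[0].matrix, cached)
        # reorder recomputed from cache: group-wise blocks are contiguous
        groups = new.matrices[0].groups
        labels = [groups[i] for i in new.ordering.permutation]
        assert labels == sorted(labels, key=lambda g: labels.index(g))

    def test_region_change_requires_full_render(self, bimodal_scenario):
        state = render(_tracks_for(bimodal_scenario),
                       bimodal_scenario.spec.region, n_bins=40)
        with pytest.raises(RequiresFullRender):
            adjust(state, region=GenomicRegion("chr2", 0, 100))
        with pytest.raises(RequiresFullRender):
            adjust(state, n_bins=10)

    def test_state_roundtrip(self, tmp_path, bimodal_scenario):
        state = render(_tracks_for(bimodal_scenario),
                       bimodal_scenario.spec.region, n_bins=40)
        p = str(tmp_path / "state.pkl")
        save_state(state, p)
        back = load_state(p)
        np.testing.assert_array_equal(
            back.matrices[0].matrix, state.matrices[0].matrix)
        np.testing.assert_array_equal(
            back.ordering.permutation, state.ordering.permutation)
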