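"""Track-based rendering of single-cell coverage in genomic context.

Five track kinds compose one figure, stacked top-to-bottom on a shared
genomic x-axis:

- ``sc_heatmap``  — per-cell read coverage as a heat map, rows reordered by
  diffusion-map (or PCA) pseudo-time, with a group color key on the left;
- ``sc_mean``     — mean coverage per cell group;
- ``bulk``        — coverage of one bulk NGS sample;
- ``bed``         — genomic intervals from a BED file;
- ``gene``        — gene models (exon boxes, intron lines, strand marks).

:func:`render` reads the source files once and returns a :class:`PlotState`
caching every coverage matrix (in input row order, with the display
permutation kept separately). :func:`adjust` restyles and re-renders from
that cache alone — it never reopens a BAM or BigWig — so iterating on the
color-scale maximum or the reordering is fast and works even after the
source files are gone.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from .coverage import (
    CoverageMatrix,
    CoverageVector,
    build_coverage_matrix,
    group_order,
    mean_coverage_by_group,
)
from .genome import FeatureInterval, GeneModel, GenomicRegion, read_bed, read_gtf_gene_models
from .ordering import CellOrdering, order_cells

__all__ = [
    "TrackSpec",
    "PlotState",
    "RequiresFullRender",
    "render",
    "adjust",
    "draw_figure",
    "resolve_vmax",
    "color_scale",
    "assign_lanes",
    "render_gene_track",
    "save_state",
    "load_state",
]

TrackKind = Literal["sc_heatmap", "sc_mean", "bulk", "bed", "gene"]

DEFAULT_HEIGHTS = {
    "sc_heatmap": 6.0,
    "sc_mean": 1.0,  # per group
    "bulk": 1.0,
    "bed": 0.5,
    "gene": 1.5,
}

# parameters adjust() may change without touching source files
STYLE_KEYS = frozenset(
    {"vmax", "cmap", "heights", "group_colors", "dpi", "reorder", "method",
     "vmax_quantile", "max_display_rows"}
)


class RequiresFullRender(Exception):
    """Raised when adjust() is asked to change region or data sources."""


@dataclass(frozen=True)
class TrackSpec:
    """Declarative description of one track.

    ``sc_heatmap``/``sc_mean`` take per-cell ``sources`` (triples of
    ``(cell_id, path, format)``) plus optional ``norm_factors``/``groups``;
    ``bulk`` takes a single ``path``/``fmt`` (and optional norm factor);
    ``bed`` takes a ``path`` or pre-parsed ``features``; ``gene`` a GTF
    ``path`` or pre-parsed ``models``. ``style`` holds kind-specific options
    (e.g. ``color`` for mean/bulk lines, ``label``).
    """

    kind: TrackKind
    sources: Optional[Sequence[tuple[str, str, str]]] = None
    path: Optional[str] = None
    fmt: Optional[str] = None
    norm_factors: Optional[Sequence[float]] = None
    groups: Optional[Sequence[str]] = None
    features: Optional[Sequence[FeatureInterval]] = None
    models: Optional[Sequence[GeneModel]] = None
    style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind in ("sc_heatmap", "sc_mean"):
            if not self.sources:
                raise ValueError(f"{self.kind} track requires per-cell sources")
        elif self.kind == "bulk":
            if not self.path:
                raise ValueError("bulk track requires a path")
        elif self.kind == "bed":
            if self.path is None and self.features is None:
                raise ValueError("bed track requires a path or features")
        elif self.kind == "gene":
            if self.path is None and self.models is None:
                raise ValueError("gene track requires a GTF path or models")
        else:
            raise ValueError(f"unknown track kind {self.kind!r}")


@dataclass
class PlotState:
    """Everything needed to re-render the last plot without re-reading data.

    ``matrices`` (keyed by track index) hold coverage in input row order;
    the display permutation lives in ``ordering``. ``params`` are the
    resolved style parameters of the last render.
    """

    region: GenomicRegion
    tracks: list[TrackSpec]
    matrices: dict[int, CoverageMatrix]
    features: dict[int, list[FeatureInterval]]
    models: dict[int, list[GeneModel]]
    ordering: Optional[CellOrdering]
    params: dict


def resolve_vmax(
    values: np.ndarray,
    vmax: Union[float, Literal["auto"]] = "auto",
    q: float = 0.99,
) -> float:
    """Resolve the color-scale maximum.

    ``"auto"`` takes the *q* upper quantile (default 0.99) of the positive
    values — a robust default so a handful of exceptionally high-coverage
    bins do not wash out the rest of the heat map — and falls back to 1.0
    when no value is positive. An explicit *vmax* must be positive.
    """
    if vmax == "auto":
        vals = np.asarray(values, dtype=float)
        pos = vals[vals > 0]
        if pos.size == 0:
            return 1.0
        return float(np.quantile(pos, q))
    v = float(vmax)
    if v <= 0:
        raise ValueError(f"vmax must be positive, got {v}")
    return v


def color_scale(
    values: np.ndarray,
    vmax: Union[float, Literal["auto"]] = "auto",
    cmap: str = "viridis",
    q: float = 0.99,
) -> np.ndarray:
    """Map non-negative values linearly onto a colormap over ``[0, vmax]``.

    Values above *vmax* saturate at the top color.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("coverage values must be non-negative")
    v = resolve_vmax(values, vmax, q=q)
    norm = matplotlib.colors.Normalize(vmin=0.0, vmax=v, clip=True)
    return matplotlib.colormaps[cmap](norm(values))


def assign_lanes(models: Sequence[GeneModel]) -> list[int]:
    """Greedy first-fit packing of transcripts onto display lanes.

    Models are processed in input order; each goes to the lowest-index lane
    where its span overlaps no transcript already placed there.
    """
    lanes: list[list[GenomicRegion]] = []
    assignment: list[int] = []
    for m in models:
        span = m.span
        placed = False
        for lane_idx, occupants in enumerate(lanes):
            if all(not span.overlaps(o) for o in occupants):
                occupants.append(span)
                assignment.append(lane_idx)
                placed = True
                break
        if not placed:
            lanes.append([span])
            assignment.append(len(lanes) - 1)
    return assignment


def render_gene_track(
    models: Sequence[GeneModel], region: GenomicRegion
) -> list[dict]:
    """Drawing commands for a gene-annotation panel.

    Returns a list of dicts: ``{"kind": "exon"|"intron"|"label", ...}`` with
    lane numbers; exons become filled boxes, the transcript span a
    connecting line carrying the strand direction. Features are clipped to
    the viewport by the renderer.
    """
    visible = [m for m in models if m.span.overlaps(region)]
    lanes = assign_lanes(visible)
    commands: list[dict] = []
    for m, lane in zip(visible, lanes):
        commands.append(
            {
                "kind": "intron",
                "lane": lane,
                "start": m.span.start,
                "end": m.span.end,
                "strand": m.strand,
                "transcript_id": m.transcript_id,
            }
        )
        for exon in m.exons:
            commands.append(
                {
                    "kind": "exon",
                    "lane": lane,
                    "start": exon.start,
                    "end": exon.end,
                    "transcript_id": m.transcript_id,
                }
            )
    return commands


def _default_group_colors(groups: Sequence[str]) -> dict[str, tuple]:
    order = group_order(groups)
    cmap = matplotlib.colormaps["tab10"]
    return {g: cmap(i % 10) for i, g in enumerate(order)}


def _load_track_data(
    tracks: Sequence[TrackSpec],
    region: GenomicRegion,
    n_bins: int,
    min_mapq: int,
) -> tuple[dict[int, CoverageMatrix], dict[int, list], dict[int, list]]:
    """Read every source file once; the only I/O phase of rendering."""
    matrices: dict[int, CoverageMatrix] = {}
    features: dict[int, list[FeatureInterval]] = {}
    models: dict[int, list[GeneModel]] = {}
    memo: dict[tuple, CoverageMatrix] = {}
    for i, t in enumerate(tracks):
        if t.kind in ("sc_heatmap", "sc_mean"):
            key = (tuple(t.sources), tuple(t.norm_factors or ()), n_bins)
            if key not in memo:
                memo[key] = build_coverage_matrix(
                    t.sources, region, n_bins,
                    norm_factors=t.norm_factors, groups=t.groups,
                    min_mapq=min_mapq,
                )
            matrices[i] = memo[key]
        elif t.kind == "bulk":
            factor = float(t.style.get("norm_factor", 1.0))
            matrices[i] = build_coverage_matrix(
                [(t.style.get("label", "bulk"), t.path, t.fmt or "bigwig")],
                region, n_bins, norm_factors=[factor], min_mapq=min_mapq,
            )
        elif t.kind == "bed":
            features[i] = (
                list(t.features) if t.features is not None
                else read_bed(t.path, region)
            )
        elif t.kind == "gene":
            models[i] = (
                list(t.models) if t.models is not None
                else read_gtf_gene_models(t.path, region)
            )
    return matrices, features, models


def _compute_ordering(
    state_matrices: dict[int, CoverageMatrix],
    tracks: Sequence[TrackSpec],
    reorder: str,
    method: str,
) -> Optional[CellOrdering]:
    """Ordering from the first heat-map track's cached matrix only."""
    for i, t in enumerate(tracks):
        if t.kind == "sc_heatmap":
            m = state_matrices[i]
            if reorder == "none" or method == "none":
                return order_cells(m, method="none")
            scope = "group_wise" if reorder == "group" else "all_cells"
            groups = m.groups
            if scope == "group_wise" and groups is None:
                groups = ["all"] * m.n_cells
                m = replace_groups(m, groups)
            return order_cells(m, method=method, scope=scope)
    return None


def replace_groups(m: CoverageMatrix, groups: Sequence[str]) -> CoverageMatrix:
    return CoverageMatrix(
        matrix=m.matrix, cell_ids=m.cell_ids, region=m.region,
        bin_edges=m.bin_edges, norm_factors=m.norm_factors, groups=list(groups),
    )


def render(
    tracks: Sequence[TrackSpec],
    region: GenomicRegion,
    out: Optional[str] = None,
    n_bins: int = 1000,
    reorder: Literal["all", "group", "none"] = "all",
    method: Literal["diffusion", "pca", "none"] = "diffusion",
    vmax: Union[float, Literal["auto"]] = "auto",
    cmap: str = "viridis",
    group_colors: Optional[dict[str, tuple]] = None,
    heights: Optional[dict[str, float]] = None,
    dpi: int = 150,
    min_mapq: int = 0,
    vmax_quantile: float = 0.99,
    max_display_rows: int = 4000,
) -> PlotState:
    """Render the full track stack and return the reusable plot state.

    Reads every source file exactly once, computes the cell ordering from
    the first heat-map track, draws all tracks aligned on the genomic
    x-axis, and (when *out* is given) writes PNG/SVG/PDF chosen by file
    extension. The returned :class:`PlotState` feeds :func:`adjust`.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("at least one track is required")
    n_bins = min(n_bins, region.width)
    matrices, features, models = _load_track_data(tracks, region, n_bins, min_mapq)
    params = {
        "n_bins": n_bins, "reorder": reorder, "method": method, "vmax": vmax,
        "cmap": cmap, "group_colors": group_colors, "heights": heights,
        "dpi": dpi, "min_mapq": min_mapq, "vmax_quantile": vmax_quantile,
        "max_display_rows": max_display_rows,
    }
    ordering = _compute_ordering(matrices, tracks, reorder, method)
    state = PlotState(
        region=region, tracks=tracks, matrices=matrices,
        features=features, models=models, ordering=ordering, params=params,
    )
    if out is not None:
        fig = draw_figure(state)
        fig.savefig(out, dpi=dpi)
        plt.close(fig)
    return state


def adjust(
    state: PlotState,
    out: Optional[str] = None,
    **overrides,
) -> PlotState:
    """Restyle and re-render from the cached matrices of the last plot.

    Only style parameters may change (color-scale max, colormap, heights,
    group colors, DPI, and the reordering method/scope — the ordering is
    then recomputed from the cached matrix alone). No BAM or BigWig file is
    reopened; asking to change the region or the data sources raises
    :class:`RequiresFullRender`.
    """
    bad = set(overrides) - STYLE_KEYS
    if bad:
        raise RequiresFullRender(
            f"adjust() can only change style parameters; got {sorted(bad)} "
            "(change of region/sources requires render())"
        )
    params = dict(state.params)
    params.update(overrides)
    ordering = state.ordering
    if ("reorder" in overrides or "method" in overrides) and overrides != {}:
        ordering = _compute_ordering(
            state.matrices, state.tracks, params["reorder"], params["method"]
        )
    new_state = PlotState(
        region=state.region, tracks=state.tracks, matrices=state.matrices,
        features=state.features, models=state.models, ordering=ordering,
        params=params,
    )
    if out is not None:
        fig = draw_figure(new_state)
        fig.savefig(out, dpi=params["dpi"])
        plt.close(fig)
    return new_state


# ---------------------------------------------------------------------------
# drawing (pure: consumes PlotState, touches no files)
# ---------------------------------------------------------------------------


def _track_height(t: TrackSpec, state: PlotState, idx: int) -> float:
    heights = state.params.get("heights") or {}
    base = heights.get(t.kind, DEFAULT_HEIGHTS[t.kind])
    if t.kind == "sc_mean":
        m = state.matrices[idx]
        n_groups = len(group_order(m.groups or ["all"] * m.n_cells))
        return base * max(n_groups, 1)
    return base


def _display_rows(matrix: np.ndarray, max_rows: int) -> np.ndarray:
    """Average adjacent (already permuted) rows when cells exceed pixels."""
    n = matrix.shape[0]
    if n <= max_rows:
        return matrix
    edges = np.linspace(0, n, max_rows + 1).astype(int)
    return np.add.reduceat(matrix, edges[:-1], axis=0) / np.diff(edges)[:, None]


def draw_figure(state: PlotState) -> Figure:
    """Draw the track stack from cached state; no source file is opened."""
    region = state.region
    p = state.params
    heights = [
        _track_height(t, state, i) for i, t in enumerate(state.tracks)
    ]
    fig_height = max(sum(heights) * 0.6, 2.0)
    fig = plt.figure(figsize=(10, fig_height))
    gs = fig.add_gridspec(
        len(state.tracks), 2, height_ratios=heights, width_ratios=[0.025, 0.975],
        hspace=0.35, wspace=0.02,
    )

    # global color scale shared by sc tracks, resolved from heat-map values
    heat_values = [
        state.matrices[i].matrix
        for i, t in enumerate(state.tracks) if t.kind == "sc_heatmap"
    ]
    vmax = resolve_vmax(
        np.concatenate([v.ravel() for v in heat_values]) if heat_values else np.array([]),
        p["vmax"], q=p.get("vmax_quantile", 0.99),
    )

    shared_ax = None
    for i, t in enumerate(state.tracks):
        key_ax = fig.add_subplot(gs[i, 0], label=f"track{i}_key")
        key_ax.set_axis_off()
        ax = fig.add_subplot(gs[i, 1], sharex=shared_ax, label=f"track{i}_main")
        if shared_ax is None:
            shared_ax = ax
        if t.kind == "sc_heatmap":
            _draw_heatmap(ax, key_ax, state, i, vmax)
        elif t.kind == "sc_mean":
            _draw_group_means(ax, state, i)
        elif t.kind == "bulk":
            _draw_bulk(ax, state, i)
        elif t.kind == "bed":
            _draw_bed(ax, state.features[i], region, t)
        elif t.kind == "gene":
            _draw_genes(ax, state.models[i], region)
        ax.set_xlim(region.start, region.end)
        if i < len(state.tracks) - 1:
            ax.tick_params(labelbottom=False)
    if shared_ax is not None:
        fig.axes[-1].set_xlabel(f"{region.chrom} position (bp)")
    return fig


def _draw_heatmap(ax, key_ax, state: PlotState, idx: int, vmax: float) -> None:
    m = state.matrices[idx]
    perm = (
        state.ordering.permutation
        if state.ordering is not None
        else np.arange(m.n_cells)
    )
    data = m.matrix[perm]
    data = _display_rows(data, state.params.get("max_display_rows", 4000))
    ax.imshow(
        data,
        aspect="auto",
        interpolation="nearest",
        extent=(m.bin_edges[0], m.bin_edges[-1], data.shape[0], 0),
        cmap=state.params["cmap"],
        vmin=0.0,
        vmax=vmax,
    )
    ax.set_yticks([])
    ax.set_ylabel(f"{m.n_cells} cells")
    if m.groups is not None:
        colors = state.params.get("group_colors") or _default_group_colors(m.groups)
        permuted = [m.groups[j] for j in perm]
        key = np.array([colors[g] for g in permuted])
        key_ax.imshow(
            key[:, None, :], aspect="auto", interpolation="nearest",
            extent=(0, 1, len(permuted), 0),
        )
        key_ax.set_xlim(0, 1)


def _draw_group_means(ax, state: PlotState, idx: int) -> None:
    m = state.matrices[idx]
    groups = m.groups or ["all"] * m.n_cells
    colors = state.params.get("group_colors") or _default_group_colors(groups)
    centers = (m.bin_edges[:-1] + m.bin_edges[1:]) / 2.0
    for label, vec in mean_coverage_by_group(m):
        ax.plot(centers, vec.values, lw=1.0, label=label,
                color=colors.get(label))
    ax.set_ylim(bottom=0)
    ax.set_ylabel("mean")
    ax.legend(fontsize="x-small", loc="upper right", frameon=False)


def _draw_bulk(ax, state: PlotState, idx: int) -> None:
    m = state.matrices[idx]
    centers = (m.bin_edges[:-1] + m.bin_edges[1:]) / 2.0
    color = state.tracks[idx].style.get("color", "0.3")
    ax.fill_between(centers, m.matrix[0], step="mid", color=color)
    ax.set_ylim(bottom=0)
    ax.set_ylabel(state.tracks[idx].style.get("label", "bulk"))


def _draw_bed(ax, features, region: GenomicRegion, track: TrackSpec) -> None:
    color = track.style.get("color", "tab:orange")
    for f in features:
        if not f.region.overlaps(region):
            continue
        ax.add_patch(
            Rectangle((f.region.start, 0.3), f.region.width, 0.4, color=color)
        )
        if f.name:
            ax.text(
                (max(f.region.start, region.start) + min(f.region.end, region.end)) / 2,
                0.85, f.name, ha="center", va="bottom", fontsize="x-small",
            )
    ax.set_ylim(0, 1.4)
    ax.set_yticks([])
    ax.set_ylabel(track.style.get("label", "features"), rotation=0,
                  ha="right", va="center", fontsize="small")


def _draw_genes(ax, models, region: GenomicRegion) -> None:
    commands = render_gene_track(models, region)
    n_lanes = 1 + max((c["lane"] for c in commands), default=0)
    for c in commands:
        y = n_lanes - 1 - c["lane"]
        if c["kind"] == "intron":
            ax.plot([c["start"], c["end"]], [y + 0.5, y + 0.5], color="k", lw=0.8)
            marker = ">" if c["strand"] == "+" else "<"
            xs = np.linspace(
                max(c["start"], region.start), min(c["end"], region.end), 7
            )[1:-1]
            ax.plot(xs, np.full(len(xs), y + 0.5), linestyle="none",
                    marker=marker, markersize=3, color="k")
        elif c["kind"] == "exon":
            ax.add_patch(
                Rectangle((c["start"], y + 0.25), c["end"] - c["start"], 0.5,
                          color="tab:blue")
            )
    ax.set_ylim(0, max(n_lanes, 1))
    ax.set_yticks([])
    ax.set_ylabel("genes", rotation=0, ha="right", va="center", fontsize="small")


# ---------------------------------------------------------------------------
# state persistence
# ---------------------------------------------------------------------------


def save_state(state: PlotState, path: str) -> None:
    """Pickle a plot state for later adjustment (e.g. by the CLI)."""
    with open(path, "wb") as fh:
        pickle.dump(state, fh, protocol=4)


def load_state(path: str) -> PlotState:
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    if not isinstance(state, PlotState):
        raise ValueError(f"{path} does not contain a plot state")
    return state
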