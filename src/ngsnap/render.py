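"""Figure rendering: classic, line and heatmap views plus gene-model glyphs.

Conventions shared by all modes: the x axis is the genomic coordinate of
the window (1-based); plus-strand signal is drawn above the zero line and
minus-strand signal below it (minus values are negated for display only);
annotation features are drawn in a dedicated bottom panel, grouped by ID
into gene models stacked on rows so that groups never collide.

Every signal or annotation panel carries a matplotlib axes *label*
("signal", "signal:+", "signal:-" or "annotation") so that panel structure
can be inspected programmatically; auxiliary axes (the heatmap color bar)
are labelled "colorbar" and do not count as panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.figure import Figure
from matplotlib.patches import Polygon, Rectangle

from .model import (
    ConfigurationError,
    CoverageTrack,
    FeatureGroup,
    FeatureStyle,
    GenomicWindow,
)

__all__ = [
    "RenderOptions",
    "render_classic",
    "render_line",
    "render_heatmap",
    "draw_annotation",
    "assign_rows",
    "write_image",
    "LINE_MODE_MAX_LIBRARIES",
    "HEATMAP_CMAP",
]

#: Hard limit of the line mode: beyond this many overlaid libraries the
#: panel is unreadable.
LINE_MODE_MAX_LIBRARIES = 16

#: White (no signal) to dark blue (maximum signal), as in the heatmap view.
HEATMAP_CMAP = LinearSegmentedColormap.from_list(
    "white_darkblue", ["#ffffff", "#08306b"]
)

#: Okabe–Ito colorblind-safe cycle for libraries.
DEFAULT_PALETTE = (
    "#0072B2",
    "#D55E00",
    "#009E73",
    "#CC79A7",
    "#E69F00",
    "#56B4E9",
    "#818181",
    "#000000",
)

OUTPUT_FORMATS = ("tiff", "jpeg", "png", "pdf")


@dataclass
class RenderOptions:
    """Options shared by the three view modes."""

    mode: str = "classic"
    scale: str = "log2"
    output_format: str = "png"
    dpi: int = 300
    width: float = 8.0
    height: float | None = None
    palette: tuple[str, ...] = DEFAULT_PALETTE
    feature_styles: dict[str, FeatureStyle] = field(default_factory=dict)
    heatmap_scale: str = "global"
    ymax: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("classic", "line", "heatmap"):
            raise ConfigurationError(f"unknown view mode {self.mode!r}")
        if self.scale not in ("log2", "linear"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.output_format not in OUTPUT_FORMATS:
            raise ConfigurationError(
                f"unknown output format {self.output_format!r}; "
                f"expected one of {list(OUTPUT_FORMATS)}"
            )
        if self.dpi <= 0:
            raise ConfigurationError(f"dpi must be positive, got {self.dpi}")
        if self.heatmap_scale not in ("global", "per-library"):
            raise ConfigurationError(
                f"unknown heatmap scale {self.heatmap_scale!r}"
            )


def _check_tracks(tracks: list[CoverageTrack]) -> GenomicWindow:
    if not tracks:
        raise ValueError("at least one coverage track is required")
    window = tracks[0].window
    for t in tracks[1:]:
        if t.window != window:
            raise ValueError(
                f"tracks cover different windows: {window} vs {t.window}"
            )
    return window


def _ylabel(tracks: list[CoverageTrack]) -> str:
    return "log2 tag density" if tracks[0].transformed else "tag density"


def _track_color(i: int, track: CoverageTrack, options: RenderOptions) -> str:
    return options.palette[i % len(options.palette)]


def _signal_ylim(track: CoverageTrack, options: RenderOptions) -> float:
    if options.ymax is not None:
        return options.ymax
    m = max(float(track.plus.max()), float(track.minus.max()))
    return m if m > 0 else 1.0


def _x(window: GenomicWindow) -> np.ndarray:
    return np.arange(window.start, window.end + 1)


def _new_figure(
    n_signal: int, options: RenderOptions, signal_ratio: float = 1.0
) -> tuple[Figure, list]:
    """A figure with n_signal stacked signal panels and one annotation panel."""
    height = options.height
    if height is None:
        height = max(2.5, 1.2 * n_signal * signal_ratio + 1.2)
    ratios = [signal_ratio] * n_signal + [0.6]
    fig, axes = plt.subplots(
        n_signal + 1,
        1,
        sharex=True,
        figsize=(options.width, height),
        gridspec_kw={"height_ratios": ratios},
        squeeze=False,
    )
    return fig, [ax for (ax,) in axes]


def render_classic(
    tracks: list[CoverageTrack],
    groups: list[FeatureGroup],
    options: RenderOptions,
) -> Figure:
    """Filled-area view: one panel per library plus the annotation panel."""
    window = _check_tracks(tracks)
    x = _x(window)
    fig, axes = _new_figure(len(tracks), options)
    for i, (track, ax) in enumerate(zip(tracks, axes)):
        color = _track_color(i, track, options)
        ax.fill_between(x, 0.0, track.plus, step="mid", color=color, linewidth=0)
        ax.fill_between(x, 0.0, -track.minus, step="mid", color=color, linewidth=0)
        ax.axhline(0.0, color="black", linewidth=0.8)
        m = _signal_ylim(track, options)
        ax.set_ylim(-1.05 * m, 1.05 * m)
        ax.set_ylabel(_ylabel(tracks), fontsize=8)
        ax.set_title(track.name, loc="left", fontsize=9)
        ax.set_label("signal")
    draw_annotation(axes[-1], groups, window, options.feature_styles)
    axes[-1].set_xlabel(f"{window.chrom} position")
    axes[-1].set_xlim(window.start - 0.5, window.end + 0.5)
    return fig


def render_line(
    tracks: list[CoverageTrack],
    groups: list[FeatureGroup],
    options: RenderOptions,
) -> Figure:
    """Overlaid-curve view: a single panel for all libraries (at most 16)."""
    window = _check_tracks(tracks)
    if len(tracks) > LINE_MODE_MAX_LIBRARIES:
        raise ValueError(
            f"line mode is limited to {LINE_MODE_MAX_LIBRARIES} libraries; "
            f"got {len(tracks)} (use heatmap mode instead)"
        )
    x = _x(window)
    fig, axes = _new_figure(1, options, signal_ratio=2.5)
    ax = axes[0]
    linestyles = ("-", "--", "-.", ":")
    for i, track in enumerate(tracks):
        color = _track_color(i, track, options)
        ls = linestyles[(i // len(options.palette)) % len(linestyles)]
        ax.plot(x, track.plus, color=color, linestyle=ls, linewidth=1.0,
                label=track.name)
        ax.plot(x, -track.minus, color=color, linestyle=ls, linewidth=1.0)
    ax.axhline(0.0, color="black", linewidth=0.8)
    m = options.ymax
    if m is None:
        m = max(_signal_ylim(t, options) for t in tracks)
    ax.set_ylim(-1.05 * m, 1.05 * m)
    ax.set_ylabel(_ylabel(tracks), fontsize=8)
    ax.legend(loc="upper right", fontsize=7, frameon=False)
    ax.set_label("signal")
    draw_annotation(axes[-1], groups, window, options.feature_styles)
    axes[-1].set_xlabel(f"{window.chrom} position")
    axes[-1].set_xlim(window.start - 0.5, window.end + 0.5)
    return fig


def render_heatmap(
    tracks: list[CoverageTrack],
    groups: list[FeatureGroup],
    options: RenderOptions,
) -> Figure:
    """Color-coded view: one panel per strand, one lane per library.

    Value 0 maps to white and the panel maximum to dark blue; with the
    default ``global`` scaling one linear color scale is shared by all
    lanes of both panels, so lanes are directly comparable.
    """
    window = _check_tracks(tracks)
    plus = np.vstack([t.plus for t in tracks])
    minus = np.vstack([t.minus for t in tracks])
    if options.heatmap_scale == "per-library":
        for mat in (plus, minus):
            for row in mat:
                m = row.max()
                if m > 0:
                    row /= m
        vmax = 1.0
    else:
        vmax = max(float(plus.max()), float(minus.max()))
        if vmax <= 0:
            vmax = 1.0

    n = len(tracks)
    height = options.height or max(2.5, 0.35 * 2 * n + 1.5)
    fig, axes = plt.subplots(
        3,
        1,
        sharex=True,
        figsize=(options.width, height),
        gridspec_kw={"height_ratios": [1.0, 1.0, 0.5]},
    )
    extent = (window.start - 0.5, window.end + 0.5, n - 0.5, -0.5)
    images = []
    for ax, mat, strand in ((axes[0], plus, "+"), (axes[1], minus, "-")):
        im = ax.imshow(
            mat,
            aspect="auto",
            interpolation="nearest",
            cmap=HEATMAP_CMAP,
            vmin=0.0,
            vmax=vmax,
            extent=extent,
        )
        images.append(im)
        ax.set_yticks(range(n))
        ax.set_yticklabels([t.name for t in tracks], fontsize=7)
        ax.set_ylabel(f"{strand} strand", fontsize=9)
        ax.set_label(f"signal:{strand}")
    cbar = fig.colorbar(
        images[0], ax=axes[:2].tolist(), fraction=0.03, pad=0.02
    )
    cbar.ax.set_label("colorbar")
    cbar.set_label(_ylabel(tracks), fontsize=8)
    draw_annotation(axes[2], groups, window, options.feature_styles)
    axes[2].set_xlabel(f"{window.chrom} position")
    axes[2].set_xlim(window.start - 0.5, window.end + 0.5)
    return fig


def assign_rows(groups: list[FeatureGroup]) -> list[int]:
    """First-fit row assignment so group spans never overlap within a row.

    Groups are processed by ascending span start (ties by the first
    member's source line); each goes to the lowest row whose rightmost
    occupied base lies strictly left of the group's span.
    """
    order = sorted(
        range(len(groups)),
        key=lambda i: (
            groups[i].span[0],
            groups[i].members[0].source_line,
        ),
    )
    rows: list[int] = [0] * len(groups)
    row_end: list[int] = []  # rightmost occupied base (1-based incl) per row
    for i in order:
        start, end = groups[i].span
        for r, occupied_until in enumerate(row_end):
            if start > occupied_until:
                rows[i] = r
                row_end[r] = end
                break
        else:
            rows[i] = len(row_end)
            row_end.append(end)
    return rows


def _style_for(ftype: str, feature_styles: dict[str, FeatureStyle]) -> FeatureStyle:
    if ftype in feature_styles:
        return feature_styles[ftype]
    return FeatureStyle(feature_type=ftype, shape="box", color="0.35")


def _tip_size(window: GenomicWindow) -> float:
    return max(1.0, 0.012 * len(window))


def _draw_member(
    ax,
    start: float,
    end: float,
    y: float,
    strand: str,
    style: FeatureStyle,
    window: GenomicWindow,
    clipped_right: bool,
    clipped_left: bool,
) -> None:
    """Draw one feature clipped to [start, end] (1-based, plot coords)."""
    h = 0.30  # half-height of filled glyphs
    x0, x1 = start - 0.5, end + 0.5
    tip = min(_tip_size(window), 0.6 * (x1 - x0))
    # Orientation glyphs are suppressed when the oriented end was clipped
    # off by the window, or when the feature is unstranded.
    oriented = strand in ("+", "-") and not (
        (strand == "+" and clipped_right) or (strand == "-" and clipped_left)
    )
    shape = style.shape
    if shape == "box" and not oriented:
        shape = "rectangle"
    if shape == "arrow" and not oriented:
        shape = "line"

    if shape == "line":
        ax.plot([x0, x1], [y, y], color=style.color, linewidth=1.2)
    elif shape == "rectangle":
        ax.add_patch(
            Rectangle((x0, y - h), x1 - x0, 2 * h, facecolor=style.color,
                      edgecolor="black", linewidth=0.5)
        )
    elif shape == "box":
        if strand == "+":
            pts = [(x0, y - h), (x1 - tip, y - h), (x1, y),
                   (x1 - tip, y + h), (x0, y + h)]
        else:
            pts = [(x1, y - h), (x0 + tip, y - h), (x0, y),
                   (x0 + tip, y + h), (x1, y + h)]
        ax.add_patch(
            Polygon(pts, closed=True, facecolor=style.color,
                    edgecolor="black", linewidth=0.5)
        )
    elif shape == "arrow":
        ax.plot([x0, x1], [y, y], color=style.color, linewidth=1.2)
        ah = 0.18
        if strand == "+":
            pts = [(x1 - tip, y - ah), (x1, y), (x1 - tip, y + ah)]
        else:
            pts = [(x0 + tip, y - ah), (x0, y), (x0 + tip, y + ah)]
        ax.add_patch(
            Polygon(pts, closed=True, facecolor=style.color,
                    edgecolor=style.color, linewidth=0.5)
        )
    else:  # pragma: no cover - vocabulary enforced by FeatureStyle
        raise ConfigurationError(f"unknown shape {shape!r}")


def draw_annotation(
    ax,
    groups: list[FeatureGroup],
    window: GenomicWindow,
    feature_styles: dict[str, FeatureStyle] | None = None,
) -> None:
    """Populate an axes with the gene models of the groups.

    Members of one group share a horizontal row; groups are stacked with
    first-fit so their spans never overlap within a row.  Features are
    clipped to the window, and the orientation glyph of a box or arrow is
    dropped when its pointed end lies outside the window.
    """
    feature_styles = feature_styles or {}
    rows = assign_rows(groups)
    for group, row in zip(groups, rows):
        y = -float(row)
        gstart, gend = group.span
        cs, ce = max(gstart, window.start), min(gend, window.end)
        if ce >= cs and len(group.members) > 1:
            # Backbone connecting the members of a multi-part model.
            ax.plot([cs - 0.5, ce + 0.5], [y, y], color="0.6",
                    linewidth=0.8, zorder=1)
        for member in group.members:
            s, e = max(member.start, window.start), min(member.end, window.end)
            if e < s:
                continue
            _draw_member(
                ax,
                s,
                e,
                y,
                group.strand,
                _style_for(member.type, feature_styles),
                window,
                clipped_right=member.end > window.end,
                clipped_left=member.start < window.start,
            )
        if ce >= cs:
            ax.text(
                (cs + ce) / 2.0, y + 0.38, group.id,
                ha="center", va="bottom", fontsize=6, clip_on=True,
            )
    n_rows = (max(rows) + 1) if rows else 1
    ax.set_ylim(-(n_rows - 1) - 0.6, 0.9)
    ax.set_yticks([])
    ax.set_label("annotation")


def panel_labels(fig: Figure) -> list[str]:
    """The labels of the figure's signal/annotation panels, in layout order."""
    return [
        ax.get_label()
        for ax in fig.axes
        if ax.get_label() in ("signal", "signal:+", "signal:-", "annotation")
    ]


def write_image(
    figure: Figure,
    path: str | PathLike,
    options: RenderOptions,
) -> str:
    """Write the figure to disk in the requested format.

    Raster formats (tiff, jpeg, png) carry resolution metadata equal to
    ``options.dpi``; pdf output is vector.
    """
    fmt = options.output_format
    if fmt not in OUTPUT_FORMATS:
        raise ConfigurationError(
            f"unknown output format {fmt!r}; expected one of {list(OUTPUT_FORMATS)}"
        )
    save_kwargs: dict = {"format": fmt, "dpi": options.dpi}
    if fmt in ("tiff", "jpeg"):
        # These go through Pillow; pass the resolution explicitly so the
        # file's metadata matches.
        save_kwargs["pil_kwargs"] = {"dpi": (options.dpi, options.dpi)}
    try:
        figure.savefig(str(path), **save_kwargs)
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
    return str(path)
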