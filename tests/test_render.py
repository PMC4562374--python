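"""View-mode contracts, annotation glyph layout and image output."""

import numpy as np
import pytest
from matplotlib import pyplot as plt
from matplotlib.image import AxesImage
from matplotlib.patches import Polygon, Rectangle
from PIL import Image

from ngsnap.coverage import compute_coverage, log2_transform
from ngsnap.model import (
    AlignedFragment,
    AnnotationFeature,
    ConfigurationError,
    FeatureGroup,
    FeatureStyle,
    GenomicWindow,
)
from ngsnap.render import (
    HEATMAP_CMAP,
    LINE_MODE_MAX_LIBRARIES,
    RenderOptions,
    assign_rows,
    draw_annotation,
    panel_labels,
    render_classic,
    render_heatmap,
    render_line,
    write_image,
)

WINDOW = GenomicWindow("chrS", 1, 200)


def luminance(rgba):
    r, g, b = rgba[:3]
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


def make_track(seed, name="lib", strand_bias=0.5, n=40):
    rng = np.random.default_rng(seed)
    frags = []
    for _ in range(n):
        s = int(rng.integers(0, 180))
        e = s + int(rng.integers(5, 20))
        strand = "+" if rng.random() < strand_bias else "-"
        frags.append(AlignedFragment(start=s, end=min(e, 200), strand=strand))
    return compute_coverage(frags, WINDOW, name=name)


def make_groups():
    feats = [
        AnnotationFeature("chrS", "gene", 20, 90, "+", "gA", 1),
        AnnotationFeature("chrS", "exon", 20, 50, "+", "gA", 2),
        AnnotationFeature("chrS", "exon", 70, 90, "+", "gA", 3),
        AnnotationFeature("chrS", "gene", 120, 180, "-", "gB", 4),
    ]
    groups = [
        FeatureGroup("gA", "+", feats[:3]),
        FeatureGroup("gB", "-", feats[3:]),
    ]
    return groups


@pytest.fixture(autouse=True)
def close_figures():
    yield
    plt.close("all")


@pytest.mark.parametrize("n_tracks", [1, 3])
def test_classic_has_one_panel_per_library_plus_annotation(n_tracks):
    tracks = [make_track(i, f"lib{i}") for i in range(n_tracks)]
    fig = render_classic(tracks, make_groups(), RenderOptions())
    labels = panel_labels(fig)
    assert labels.count("signal") == n_tracks
    assert labels.count("annotation") == 1


def test_classic_minus_only_signal_stays_below_zero():
    frags = [AlignedFragment(start=10, end=60, strand="-")] * 5
    track = compute_coverage(frags, WINDOW)
    fig = render_classic([track], [], RenderOptions())
    ax = fig.axes[0]
    for coll in ax.collections:
        verts = np.concatenate([p.vertices for p in coll.get_paths()])
        assert verts[:, 1].max() <= 1e-9


def test_classic_rejects_mismatched_windows():
    t1 = make_track(1)
    other = GenomicWindow("chrS", 1, 100)
    t2 = compute_coverage([], other)
    with pytest.raises(ValueError, match="different windows"):
        render_classic([t1, t2], [], RenderOptions())


def test_line_mode_single_panel_and_strand_sides():
    tracks = [make_track(i, f"lib{i}") for i in range(3)]
    fig = render_line(tracks, make_groups(), RenderOptions())
    labels = panel_labels(fig)
    assert labels == ["signal", "annotation"]
    ax = fig.axes[0]
    data_lines = [ln for ln in ax.lines if len(ln.get_xdata()) == len(WINDOW)]
    assert len(data_lines) == 2 * len(tracks)  # one per (library, strand)
    minus_lines = [ln for ln in data_lines if ln.get_ydata().min() < 0]
    for ln in minus_lines:
        assert ln.get_ydata().max() <= 0


def test_line_mode_enforces_library_limit():
    tracks17 = [make_track(i) for i in range(LINE_MODE_MAX_LIBRARIES + 1)]
    with pytest.raises(ValueError, match="16"):
        render_line(tracks17, [], RenderOptions())
    fig = render_line(tracks17[:LINE_MODE_MAX_LIBRARIES], [], RenderOptions())
    assert panel_labels(fig) == ["signal", "annotation"]


def test_heatmap_two_strand_panels_many_libraries():
    tracks = [make_track(i, f"lib{i}") for i in range(30)]
    fig = render_heatmap(tracks, make_groups(), RenderOptions())
    labels = panel_labels(fig)
    assert labels == ["signal:+", "signal:-", "annotation"]
    for ax in fig.axes[:2]:
        im = next(a for a in ax.get_children() if isinstance(a, AxesImage))
        assert im.get_array().shape == (30, len(WINDOW))


def test_heatmap_zero_maps_to_white_and_shared_scale():
    zero = compute_coverage([], WINDOW, name="empty")
    busy = make_track(4, "busy")
    fig = render_heatmap([zero, busy], [], RenderOptions())
    ims = [
        next(a for a in ax.get_children() if isinstance(a, AxesImage))
        for ax in fig.axes[:2]
    ]
    for im in ims:
        rgba = im.cmap(im.norm(0.0))
        assert rgba[:3] == pytest.approx((1.0, 1.0, 1.0))
    assert ims[0].norm.vmax == ims[1].norm.vmax


def test_heatmap_colormap_luminance_monotone_decreasing():
    values = np.linspace(0, 1, 50)
    lums = [luminance(HEATMAP_CMAP(v)) for v in values]
    assert all(a > b for a, b in zip(lums, lums[1:]))


def test_heatmap_darkest_cell_is_the_track_maximum():
    track = make_track(12, "m", strand_bias=1.0)
    fig = render_heatmap([track], [], RenderOptions())
    ax = fig.axes[0]
    im = next(a for a in ax.get_children() if isinstance(a, AxesImage))
    data = np.asarray(im.get_array())
    rgba = im.cmap(im.norm(data))
    lums = 0.2126 * rgba[..., 0] + 0.7152 * rgba[..., 1] + 0.0722 * rgba[..., 2]
    # independent scan for the maximum of the underlying track
    argmax = int(np.argmax(track.plus))
    assert int(np.argmin(lums[0])) == argmax


class TestAnnotationLayout:
    def test_non_overlapping_groups_share_row_zero(self):
        groups = make_groups()
        assert assign_rows(groups) == [0, 0]

    def test_random_rows_have_no_horizontal_overlap(self):
        rng = np.random.default_rng(31)
        groups = []
        for i in range(40):
            start = int(rng.integers(1, 1000))
            end = start + int(rng.integers(10, 200))
            feat = AnnotationFeature("chrS", "gene", start, end, "+",
                                     f"g{i}", i + 1)
            groups.append(FeatureGroup(f"g{i}", "+", [feat]))
        rows = assign_rows(groups)
        by_row = {}
        for g, r in zip(groups, rows):
            by_row.setdefault(r, []).append(g.span)
        for spans in by_row.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2  # pairwise disjoint within a row

    def test_plus_box_is_polygon_with_rightward_tip(self):
        feat = AnnotationFeature("chrS", "gene", 50, 120, "+", "g", 1)
        group = FeatureGroup("g", "+", [feat])
        fig, ax = plt.subplots()
        draw_annotation(ax, [group], WINDOW,
                        {"gene": FeatureStyle("gene", "box", "red")})
        polys = [p for p in ax.patches if isinstance(p, Polygon)]
        assert len(polys) == 1
        xs = polys[0].get_xy()[:, 0]
        assert xs.max() == pytest.approx(120.5)

    def test_orientation_glyph_suppressed_when_clipped(self):
        # + strand box whose right (oriented) end lies beyond the window
        feat = AnnotationFeature("chrS", "gene", 150, 400, "+", "g", 1)
        group = FeatureGroup("g", "+", [feat])
        fig, ax = plt.subplots()
        draw_annotation(ax, [group], WINDOW,
                        {"gene": FeatureStyle("gene", "box", "red")})
        assert not [p for p in ax.patches if isinstance(p, Polygon)]
        rects = [p for p in ax.patches if isinstance(p, Rectangle)]
        assert len(rects) == 1
        assert rects[0].get_x() + rects[0].get_width() <= 200.5 + 1e-9

    def test_unknown_shape_token_rejected(self):
        with pytest.raises(ConfigurationError, match="blob"):
            FeatureStyle("gene", "blob", "red")


class TestWriteImage:
    @pytest.mark.parametrize("fmt,ext", [
        ("png", "png"), ("jpeg", "jpg"), ("tiff", "tif"), ("pdf", "pdf"),
    ])
    def test_all_formats_parse(self, tmp_path, fmt, ext):
        track = make_track(2)
        opts = RenderOptions(output_format=fmt)
        fig = render_classic([track], [], opts)
        path = tmp_path / f"out.{ext}"
        write_image(fig, path, opts)
        if fmt == "pdf":
            assert path.read_bytes()[:5] == b"%PDF-"
        else:
            with Image.open(path) as img:
                assert img.format.lower() in (fmt, "jpeg")
                dpi = img.info.get("dpi")
                assert dpi is not None
                assert round(float(dpi[0])) == 300

    def test_repeat_write_is_pixel_stable(self, tmp_path):
        track = make_track(8)
        opts = RenderOptions(output_format="png")
        fig = render_classic([track], make_groups(), opts)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        write_image(fig, p1, opts)
        write_image(fig, p2, opts)
        with Image.open(p1) as i1, Image.open(p2) as i2:
            assert i1.size == i2.size
            assert np.array_equal(np.asarray(i1), np.asarray(i2))

    def test_unwritable_path_raises(self, tmp_path):
        track = make_track(1)
        opts = RenderOptions()
        fig = render_classic([track], [], opts)
        with pytest.raises(OSError):
            write_image(fig, tmp_path / "no" / "dir" / "x.png", opts)

    def test_unknown_format_rejected(self):
        with pytest.raises(ConfigurationError):
            RenderOptions(output_format="bmp")
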