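"""Per-base, strand-specific coverage tracks.

Coverage is the number of fragments whose aligned blocks overlap each base
of the window, computed separately for the plus and minus strands and
multiplied by the library's normalization weight.  Tracks can then be put
on a log2 scale (``log2(1 + v)``, so empty positions stay exactly at the
zero baseline).  Weights are applied to raw counts, before the transform,
so they act as count normalization factors.
"""

from __future__ import annotations

from typing import Iterable, TextIO

import numpy as np

from .model import AlignedFragment, CoverageTrack, GenomicWindow

__all__ = ["compute_coverage", "log2_transform", "write_bedgraph"]


def compute_coverage(
    fragments: Iterable[AlignedFragment],
    window: GenomicWindow,
    weight: float = 1.0,
    name: str = "",
) -> CoverageTrack:
    """Tally weighted per-base coverage of the fragments over the window.

    Every fragment must already intersect the window (upstream clipping);
    a fragment wholly outside it raises ``ValueError``.
    """
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    n = len(window)
    plus = np.zeros(n)
    minus = np.zeros(n)
    lane = {"+": plus, "-": minus}
    for frag in fragments:
        if not window.overlaps0(frag.start, frag.end):
            raise ValueError(
                f"fragment [{frag.start}, {frag.end}) lies outside window "
                f"{window}; fragments must be clipped before coverage"
            )
        track = lane[frag.strand]
        for s, e in frag.blocks:
            lo = max(s, window.start0) - window.start0
            hi = min(e, window.end0) - window.start0
            if hi > lo:
                track[lo:hi] += 1.0
    plus *= weight
    minus *= weight
    return CoverageTrack(
        window=window,
        plus=plus,
        minus=minus,
        name=name,
        weight_applied=weight,
        transformed=False,
    )


def log2_transform(track: CoverageTrack) -> CoverageTrack:
    """Return a copy of the track with every value v replaced by log2(1+v).

    The transform is strictly increasing and fixes 0, so empty positions
    remain on the zero baseline of the plots.  Transforming twice is an
    error.
    """
    if track.transformed:
        raise ValueError("track is already log2-transformed")
    return CoverageTrack(
        window=track.window,
        plus=np.log2(1.0 + track.plus),
        minus=np.log2(1.0 + track.minus),
        name=track.name,
        weight_applied=track.weight_applied,
        transformed=True,
    )


def write_bedgraph(track: CoverageTrack, handle: TextIO, strand: str = "+") -> None:
    """Export one strand of a track as bedGraph (0-based half-open).

    Consecutive bases with an identical value are merged into one record;
    zero-valued runs are omitted, as is conventional.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    values = track.plus if strand == "+" else track.minus
    chrom = track.window.chrom
    base0 = track.window.start0
    run_start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[run_start]:
            v = values[run_start]
            if v != 0:
                out = int(v) if float(v).is_integer() else float(v)
                handle.write(
                    f"{chrom}\t{base0 + run_start}\t{base0 + i}\t{out}\n"
                )
            run_start = i
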