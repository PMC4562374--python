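"""Extraction of strand-assigned fragments from indexed BAM files.

A library is reduced to a sequence of :class:`~ngsnap.model.AlignedFragment`
restricted to the requested window.  Single-end reads map one-to-one to
fragments; for paired-end data each proper pair becomes exactly one fragment
spanning from the leftmost mate start to the rightmost mate end, with
coverage contributed only by the mates' aligned blocks (splice gaps and the
unsequenced inner gap are excluded unless ``fill_pair_gap`` is set).

Record filtering: unmapped, secondary, supplementary and QC-fail records are
always excluded; duplicates are kept, as coverage displays conventionally
show them.  In paired layout only proper pairs are used — orphan mates are
dropped.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterator

import pysam

from .model import (
    AlignedFragment,
    GenomicWindow,
    Layout,
    LibrarySpec,
    Strandedness,
)

__all__ = ["assign_fragment_strand", "load_fragments"]

log = logging.getLogger(__name__)

_FLIP = {"+": "-", "-": "+"}


def assign_fragment_strand(
    mapping_strand: str,
    is_second_mate: bool,
    strandedness: Strandedness | str,
) -> str:
    """Deduce the originating fragment's strand from a read's mapping strand.

    Parameters
    ----------
    mapping_strand
        Reference strand the read aligned to, ``"+"`` or ``"-"``.
    is_second_mate
        True for the second-in-pair mate, whose orientation is opposite to
        the fragment's under both stranded protocols.
    strandedness
        Library protocol; see :class:`~ngsnap.model.Strandedness`.

    Returns
    -------
    ``"+"`` or ``"-"``.
    """
    strandedness = Strandedness.from_token(strandedness)
    if mapping_strand not in _FLIP:
        raise ValueError(f"mapping strand must be '+' or '-', got {mapping_strand!r}")
    if strandedness is Strandedness.UNSTRANDED:
        return "+"
    effective = _FLIP[mapping_strand] if is_second_mate else mapping_strand
    if strandedness is Strandedness.FORWARD:
        return effective
    return _FLIP[effective]


def _keep(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_qcfail
    )


def _clip_blocks(
    blocks: list[tuple[int, int]], window: GenomicWindow
) -> tuple[tuple[int, int], ...]:
    """Clip, merge and sort aligned blocks against the window; may be empty."""
    clipped = []
    for s, e in sorted(blocks):
        s, e = max(s, window.start0), min(e, window.end0)
        if e <= s:
            continue
        if clipped and s <= clipped[-1][1]:
            clipped[-1] = (clipped[-1][0], max(clipped[-1][1], e))
        else:
            clipped.append((s, e))
    return tuple(clipped)


def _fragment(
    blocks: list[tuple[int, int]],
    strand: str,
    window: GenomicWindow,
    fill_gaps: bool,
) -> AlignedFragment | None:
    if fill_gaps and blocks:
        blocks = [(min(s for s, _ in blocks), max(e for _, e in blocks))]
    clipped = _clip_blocks(blocks, window)
    if not clipped:
        return None
    return AlignedFragment(
        start=clipped[0][0], end=clipped[-1][1], strand=strand, blocks=clipped
    )


def _check_chrom(bam: pysam.AlignmentFile, chrom: str, path: str) -> None:
    if chrom not in bam.references:
        names = ", ".join(bam.references[:20])
        more = "" if bam.nreferences <= 20 else f" (+{bam.nreferences - 20} more)"
        raise ValueError(
            f"chromosome {chrom!r} not found in {path}; "
            f"available: {names}{more}"
        )


def _single_end_fragments(
    bam: pysam.AlignmentFile,
    window: GenomicWindow,
    strandedness: Strandedness,
    fill_pair_gap: bool,
) -> Iterator[AlignedFragment]:
    for read in bam.fetch(window.chrom, window.start0, window.end0):
        if not _keep(read):
            continue
        strand = assign_fragment_strand(
            "-" if read.is_reverse else "+", False, strandedness
        )
        frag = _fragment(read.get_blocks(), strand, window, fill_pair_gap)
        if frag is not None:
            yield frag


def _paired_fragments(
    bam: pysam.AlignmentFile,
    window: GenomicWindow,
    strandedness: Strandedness,
    fill_pair_gap: bool,
) -> Iterator[AlignedFragment]:
    # First pass: collect both mates of every proper pair touching the
    # window.  Each pair is keyed by query name so it is emitted once even
    # when both mates overlap the window.
    pairs: dict[str, dict[bool, pysam.AlignedSegment]] = {}
    any_paired = False
    for read in bam.fetch(window.chrom, window.start0, window.end0):
        if not _keep(read):
            continue
        if read.is_paired:
            any_paired = True
        if not (read.is_paired and read.is_proper_pair):
            continue
        pairs.setdefault(read.query_name, {})[read.is_read2] = read

    if not any_paired and pairs == {}:
        # Declared paired but the file carries no pairing flags: fall back
        # to single-end handling so the user still gets a figure.
        has_reads = any(
            _keep(r) for r in bam.fetch(window.chrom, window.start0, window.end0)
        )
        if has_reads:
            warnings.warn(
                "library declared paired but no paired flags found; "
                "treating reads as single-end",
                stacklevel=3,
            )
            yield from _single_end_fragments(
                bam, window, strandedness, fill_pair_gap
            )
            return

    for qname, mates in sorted(pairs.items()):
        # Recover a mate lying outside the fetch region via its recorded
        # coordinates so the pair still counts exactly once.
        if len(mates) == 1:
            present = next(iter(mates.values()))
            try:
                other = bam.mate(present)
            except ValueError:
                log.warning("mate of proper pair %s not found; pair skipped", qname)
                continue
            mates[other.is_read2] = other
        first = mates.get(False)
        second = mates.get(True)
        if first is None or second is None:
            log.warning("pair %s lacks a first/second mate; skipped", qname)
            continue
        strand = assign_fragment_strand(
            "-" if first.is_reverse else "+", False, strandedness
        )
        blocks = first.get_blocks() + second.get_blocks()
        frag = _fragment(blocks, strand, window, fill_pair_gap)
        if frag is not None:
            yield frag


def load_fragments(
    library: LibrarySpec,
    window: GenomicWindow,
    fill_pair_gap: bool = False,
) -> list[AlignedFragment]:
    """Load the fragments of one library overlapping the window.

    Parameters
    ----------
    library
        The library to read; ``library.path`` must be a coordinate-sorted,
        indexed BAM file.
    window
        Region of interest; fragments are clipped to it.
    fill_pair_gap
        If True, a fragment covers its full outer span including splice
        gaps and the gap between paired mates; by default only aligned
        blocks contribute coverage.

    Returns
    -------
    list of :class:`~ngsnap.model.AlignedFragment`, one per retained read
    (single layout) or proper pair (paired layout).
    """
    try:
        bam = pysam.AlignmentFile(str(library.path), "rb")
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot open alignment file {library.path}: {exc}") from exc
    with bam:
        if not bam.has_index():
            raise OSError(f"alignment file {library.path} has no index (.bai)")
        _check_chrom(bam, window.chrom, str(library.path))
        if library.layout is Layout.PAIRED:
            frags = list(
                _paired_fragments(bam, window, library.strandedness, fill_pair_gap)
            )
        else:
            frags = list(
                _single_end_fragments(bam, window, library.strandedness, fill_pair_gap)
            )
    log.info(
        "%s: %d fragments in %s", library.name, len(frags), window
    )
    return frags
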