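"""Windowed loading and ID-grouping of GFF annotation features.

The loader streams a GFF2/GFF3 file line by line and materializes only the
features that overlap the requested window (and, optionally, whose type is
in a user-selected set) — no database is built, so arbitrarily large
annotation files cost only a scan.  Features sharing an identifier (exons,
UTRs, CDS of one transcript) are then grouped into gene models for
rendering.

Identifier extraction tolerates both GFF dialects: the GFF3 ``ID=``
attribute is preferred, then ``Parent=``, then a GFF2-style leading
``key value`` pair; a feature with no usable attribute gets a synthesized
unique id so it still renders, alone.
"""

from __future__ import annotations

import logging
import warnings
from os import PathLike

from .model import AnnotationFeature, FeatureGroup, GenomicWindow

__all__ = ["load_features", "group_features", "extract_id"]

log = logging.getLogger(__name__)


def extract_id(attributes: str, line_number: int) -> str:
    """Pull a grouping identifier out of a GFF attribute column."""
    attributes = attributes.strip()
    # GFF3: semicolon-separated key=value pairs.
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:].strip().strip('"')
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("Parent="):
            return part[7:].strip().strip('"')
    # GFF2: space-separated "key value" pairs.
    first = attributes.split(";")[0].strip()
    if first and "=" not in first:
        fields = first.split(None, 1)
        if len(fields) == 2:
            return fields[1].strip().strip('"')
    return f"__anon{line_number}"


def load_features(
    path: str | PathLike,
    window: GenomicWindow,
    selected_types: set[str] | None = None,
) -> list[AnnotationFeature]:
    """Load the features of a GFF file overlapping the window.

    Parameters
    ----------
    path
        A 9-column, tab-separated GFF2/GFF3 file.  ``#`` comment lines,
        ``##`` directives and blank lines are skipped; a malformed line
        triggers a warning with its line number and is skipped.
    window
        Features are kept iff their 1-based inclusive ``[start, end]``
        interval overlaps it.  They are kept whole (clipping happens at
        render time).
    selected_types
        If given, only features whose type column is in this set are kept.
    """
    features: list[AnnotationFeature] = []
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read annotation file {path}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                # Embedded FASTA section terminates the feature table.
                break
            cols = line.split("\t")
            if len(cols) != 9:
                warnings.warn(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(cols)}; line skipped",
                    stacklevel=2,
                )
                continue
            seqid, _source, ftype, start_s, end_s, _score, strand = cols[:7]
            attributes = cols[8]
            if seqid != window.chrom:
                continue
            if selected_types is not None and ftype not in selected_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                warnings.warn(
                    f"{path}: line {lineno}: non-numeric coordinates; "
                    "line skipped",
                    stacklevel=2,
                )
                continue
            if end < window.start or start > window.end:
                continue
            features.append(
                AnnotationFeature(
                    seqid=seqid,
                    type=ftype,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else ".",
                    id=extract_id(attributes, lineno),
                    source_line=lineno,
                )
            )
    log.info("%s: %d features overlap %s", path, len(features), window)
    return features


def group_features(features: list[AnnotationFeature]) -> list[FeatureGroup]:
    """Partition features by identifier into renderable gene models.

    Each distinct id yields one group; members are ordered by
    ``(start, source_line)`` and the group list by span start (then id, for
    a deterministic layout).  A group mixing strands keeps the strand of
    its first member and emits a warning.
    """
    by_id: dict[str, list[AnnotationFeature]] = {}
    for feat in features:
        by_id.setdefault(feat.id, []).append(feat)
    groups = []
    for fid, members in by_id.items():
        members = sorted(members, key=lambda f: (f.start, f.source_line))
        strands = {m.strand for m in members}
        if len(strands) > 1:
            warnings.warn(
                f"features with id {fid!r} lie on mixed strands "
                f"({sorted(strands)}); using the first member's",
                stacklevel=2,
            )
        groups.append(FeatureGroup(id=fid, strand=members[0].strand, members=members))
    groups.sort(key=lambda g: (g.span[0], g.id))
    return groups
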