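"""Seeded synthetic datasets with known ground truth.

Generates a coordinate-sorted, indexed BAM file, a GFF3 annotation file and
a plain-text placement log on a single synthetic chromosome, so every other
module can be exercised without external data.  Read sequences are
uninformative ('A' runs): only coordinates and flags matter for coverage.

The placement log records, for every record written, the quantity a loader
should reconstruct — the fragment's outer span, its aligned blocks and the
mapping strand of the (first-in-pair) read — making it the ground truth for
round-trip tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pysam

__all__ = [
    "SyntheticSpec",
    "Placement",
    "SyntheticDataset",
    "generate_synthetic_dataset",
    "read_placement_log",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Counts are per strand: ``n_single`` single-end reads and ``n_pairs``
    proper pairs are placed on *each* of the two strands.  ``inner_size``
    is the unsequenced gap between the two mates of a pair.  ``n_orphans``
    adds paired reads whose mate is unmapped (not proper pairs) and
    ``n_secondary`` adds secondary alignments; both must be ignored by a
    spec-conforming loader.
    """

    chrom: str = "chrS"
    chrom_length: int = 10_000
    read_length: int = 50
    n_single: int = 0
    n_pairs: int = 0
    inner_size: int = 100
    n_orphans: int = 0
    n_secondary: int = 0
    n_feature_ids: int = 0
    features_per_id: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_single", "n_pairs", "n_orphans", "n_secondary",
                     "n_feature_ids", "features_per_id", "inner_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length > self.chrom_length:
            raise ValueError(
                f"read length {self.read_length} exceeds chromosome "
                f"length {self.chrom_length}"
            )
        pair_span = 2 * self.read_length + self.inner_size
        if self.n_pairs > 0 and pair_span > self.chrom_length:
            raise ValueError(
                f"pair span {pair_span} exceeds chromosome length "
                f"{self.chrom_length}"
            )


@dataclass(frozen=True)
class Placement:
    """Ground truth for one written record (or pair of records)."""

    qname: str
    kind: str  # single | pair | orphan | secondary
    strand: str  # mapping strand of the read / first-in-pair mate
    start: int  # 0-based inclusive outer span start
    end: int  # 0-based exclusive outer span end
    blocks: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SyntheticDataset:
    bam_path: Path
    gff_path: Path
    log_path: Path
    placements: tuple[Placement, ...]


def _format_blocks(blocks: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in blocks)


def _parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _segment(
    header: pysam.AlignmentHeader,
    qname: str,
    flag: int,
    pos: int,
    length: int,
    mate_pos: int = -1,
    tlen: int = 0,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = qname
    seg.flag = flag
    seg.reference_id = 0
    seg.reference_start = pos
    seg.mapping_quality = 60
    seg.cigarstring = f"{length}M"
    seg.query_sequence = "A" * length
    seg.query_qualities = pysam.qualitystring_to_array("I" * length)
    seg.next_reference_id = 0 if mate_pos >= 0 else -1
    seg.next_reference_start = mate_pos
    seg.template_length = tlen
    return seg


def generate_synthetic_dataset(
    spec: SyntheticSpec, outdir: str | PathLike
) -> SyntheticDataset:
    """Write the BAM (+index), GFF3 and placement log described by ``spec``.

    The same spec (including seed) always produces byte-identical logs and
    record sets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": spec.chrom, "LN": spec.chrom_length}],
        }
    )

    segments: list[pysam.AlignedSegment] = []
    placements: list[Placement] = []

    # Single-end reads, n_single per strand.
    for strand in "+-":
        for i in range(spec.n_single):
            pos = int(rng.integers(0, spec.chrom_length - rl + 1))
            qname = f"single_{'p' if strand == '+' else 'm'}_{i:05d}"
            flag = 0 if strand == "+" else 0x10
            segments.append(_segment(header, qname, flag, pos, rl))
            placements.append(
                Placement(qname, "single", strand, pos, pos + rl,
                          ((pos, pos + rl),))
            )

    # Proper pairs in FR orientation, n_pairs per first-mate strand.
    span = 2 * rl + spec.inner_size
    for strand in "+-":
        for i in range(spec.n_pairs):
            left = int(rng.integers(0, spec.chrom_length - span + 1))
            right = left + rl + spec.inner_size
            qname = f"pair_{'p' if strand == '+' else 'm'}_{i:05d}"
            if strand == "+":
                # first mate forward at left, second mate reverse at right
                segments.append(
                    _segment(header, qname, 0x1 | 0x2 | 0x20 | 0x40,
                             left, rl, mate_pos=right, tlen=span)
                )
                segments.append(
                    _segment(header, qname, 0x1 | 0x2 | 0x10 | 0x80,
                             right, rl, mate_pos=left, tlen=-span)
                )
            else:
                # second mate forward at left, first mate reverse at right
                segments.append(
                    _segment(header, qname, 0x1 | 0x2 | 0x20 | 0x80,
                             left, rl, mate_pos=right, tlen=span)
                )
                segments.append(
                    _segment(header, qname, 0x1 | 0x2 | 0x10 | 0x40,
                             right, rl, mate_pos=left, tlen=-span)
                )
            placements.append(
                Placement(
                    qname, "pair", strand, left, left + span,
                    ((left, left + rl), (right, right + rl)),
                )
            )

    # Orphans: paired flag set, mate unmapped, NOT proper-paired.
    for i in range(spec.n_orphans):
        pos = int(rng.integers(0, spec.chrom_length - rl + 1))
        qname = f"orphan_{i:05d}"
        segments.append(
            _segment(header, qname, 0x1 | 0x8 | 0x40, pos, rl)
        )
        placements.append(
            Placement(qname, "orphan", "+", pos, pos + rl, ((pos, pos + rl),))
        )

    # Secondary alignments of otherwise ordinary single-end reads.
    for i in range(spec.n_secondary):
        pos = int(rng.integers(0, spec.chrom_length - rl + 1))
        qname = f"secondary_{i:05d}"
        segments.append(_segment(header, qname, 0x100, pos, rl))
        placements.append(
            Placement(qname, "secondary", "+", pos, pos + rl,
                      ((pos, pos + rl),))
        )

    segments.sort(key=lambda s: (s.reference_start, s.query_name, s.flag))
    bam_path = outdir / "synthetic.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.index(str(bam_path))

    gff_path = outdir / "synthetic.gff3"
    _write_gff(gff_path, spec, rng)

    log_path = outdir / "placements.tsv"
    with open(log_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["qname", "kind", "strand", "start", "end", "blocks"])
        for p in placements:
            writer.writerow(
                [p.qname, p.kind, p.strand, p.start, p.end,
                 _format_blocks(p.blocks)]
            )

    return SyntheticDataset(
        bam_path=bam_path,
        gff_path=gff_path,
        log_path=log_path,
        placements=tuple(placements),
    )


def _write_gff(path: Path, spec: SyntheticSpec, rng: np.random.Generator) -> None:
    lines = ["##gff-version 3"]
    types = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")
    for i in range(spec.n_feature_ids):
        fid = f"gene{i:04d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        span = int(rng.integers(200, max(201, spec.chrom_length // 5)))
        start = int(rng.integers(1, max(2, spec.chrom_length - span)))
        end = start + span
        lines.append(
            f"{spec.chrom}\tngsnap\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={fid};Name={fid}"
        )
        n_parts = max(1, spec.features_per_id - 1)
        cuts = sorted(
            int(rng.integers(start, end + 1)) for _ in range(2 * n_parts)
        )
        for j in range(n_parts):
            s, e = cuts[2 * j], cuts[2 * j + 1]
            if e <= s:
                e = s + 1
            ftype = types[int(rng.integers(0, len(types)))]
            lines.append(
                f"{spec.chrom}\tngsnap\t{ftype}\t{s}\t{min(e, end)}\t.\t"
                f"{strand}\t.\tID={fid}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_placement_log(path: str | PathLike) -> tuple[Placement, ...]:
    """Parse a placement log back into :class:`Placement` records."""
    out = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            out.append(
                Placement(
                    qname=row["qname"],
                    kind=row["kind"],
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    blocks=_parse_blocks(row["blocks"]),
                )
            )
    return tuple(out)
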