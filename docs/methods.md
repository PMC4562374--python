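# Methods

## Coordinate conventions

User-facing coordinates (the `--window` string, GFF features) are 1-based
inclusive, matching GFF and genome-browser habit. Internally every interval
is 0-based half-open, the BAM convention. The conversion happens exactly
once, when `GenomicWindow` is constructed; `start0`/`end0` expose the
internal form.

## Fragment model

The unit of coverage is the sequenced *fragment*, not the read.

- **Single-end:** one read → one fragment; its aligned blocks (CIGAR match
  segments) are the covered intervals, so spliced RNA-seq reads contribute
  nothing across skipped introns.
- **Paired-end:** one proper pair → one fragment spanning leftmost mate
  start to rightmost mate end. Covered intervals are the union of both
  mates' aligned blocks; the unsequenced inner gap is excluded by default
  because filling it would paint intron-like signal between mates. The
  alternative behaviour (template-span fill) is available with
  `--fill-pair-gap`, which some applications (e.g. chromatin fragments)
  prefer.

Record filtering: unmapped, secondary, supplementary and QC-fail records
are always dropped. Duplicates are kept — coverage displays conventionally
show them unless deduplication was done upstream. In paired layout only
proper-pair-flagged records are used; orphan mates are dropped. A pair is
emitted exactly once, keyed by query name; when only one mate overlaps the
fetch window the other is recovered through the index via its recorded mate
coordinates. If a library is declared paired but the file carries no
pairing flags at all, a warning is emitted and reads are treated as
single-end rather than failing the run.

## Strandedness

`strandedness` describes the protocol-determined relation between a read's
mapping strand and the transcribed strand of its fragment. The protocol is
always evaluated on the first-in-pair mate (for pairs) or the read itself
(single-end). The full decision table, including the second-mate flip used
when reasoning about individual mates:

| mapping strand | second mate? | unstranded | forward | reverse |
|---|---|---|---|---|
| + | no  | + | + | − |
| − | no  | + | − | + |
| + | yes | + | − | + |
| − | yes | + | + | − |

`unstranded` collapses all signal to the plus strand (appropriate for
ChIP-seq and similar); `forward` suits ligation protocols; `reverse` suits
the common dUTP protocol.

## Coverage and scaling

For each window base and strand, coverage is the count of fragments whose
aligned blocks cover the base, multiplied by the library's weight. Weights
are per-library normalization factors (size factors, RPM factors) computed
externally — the package deliberately does not estimate them. They are
applied to raw counts *before* any transform, so they act on counts, not on
log values. Values stay floating-point; nothing is rounded.

The display scale is `log2` by default: v ↦ log₂(1 + v), which is strictly
increasing and maps 0 to 0, so empty positions sit on the zero baseline of
the classic/line views and on white in the heatmap. Plain `linear` scale is
available. The +1 shift is a choice: plotting log₂(v) with masked zeros
would leave gaps wherever coverage drops to zero and make filled areas
discontinuous.

Each strand of a track can be exported as bedGraph (0-based half-open,
zero runs omitted) for cross-tool comparison.

## Annotation handling

The GFF loader is a streaming line scanner: it materializes only features
that overlap the window (and, optionally, whose type is in a user-selected
set), so annotation files of any size cost a single scan and no database.
Malformed lines are skipped with a warning naming the line number;
`#` comments, `##` directives and a trailing FASTA section are ignored.

Grouping key, in order of preference: GFF3 `ID=`, then `Parent=`, then a
GFF2-style leading `key value` pair; a feature with no usable attribute
gets a synthesized unique `__anon<line>` id so it still renders, alone.
Features sharing a key form one gene model; members are ordered by
(start, input line), groups by span start. A group mixing strands keeps
its first member's strand and warns. Features straddling the window edge
are kept whole for grouping and clipped only at render time.

## Rendering

Shared conventions: x axis in genomic coordinates of the window; plus
strand above the zero line, minus strand below (values negated for display
only); a colorblind-safe Okabe–Ito palette cycles over libraries; gene
models are drawn in a dedicated bottom panel.

- **classic** — one filled-area panel per library plus the annotation
  panel. Y limits are symmetric about 0 at the larger of the two strand
  maxima (override: `--ymax`), so the baseline is centered.
- **line** — a single panel with one curve per (library, strand). Capped
  at 16 libraries; beyond that the overlay is unreadable and the call is
  rejected before any drawing.
- **heatmap** — two panels (+ and − strand), one horizontal lane per
  library, no library limit. The color ramp runs white (0) → dark blue
  (maximum) with luminance strictly decreasing in value. By default one
  linear scale spans the maximum over all lanes of both panels so lanes
  are visually comparable (`--heatmap-scale global`); `per-library`
  rescales each lane to its own maximum instead.

Gene-model glyphs per feature type: `box` (rectangle with a pointed end
showing orientation), `rectangle`, `arrow` (line with arrowhead), `line`.
Orientation glyphs point along the group's strand and are suppressed when
the oriented end was clipped off by the window, or when the feature is
unstranded. Groups are stacked with first-fit by span start (ties by input
line), so spans never overlap within a row. Panels carry matplotlib axes
labels (`signal`, `signal:+`, `signal:-`, `annotation`; the heatmap color
bar is `colorbar`) so figure structure is programmatically checkable.

Output: tiff/jpeg/png rasters carry resolution metadata equal to the
requested dpi (default 300); pdf is vector. Note PNG stores resolution as
dots-per-metre, so 300 dpi reads back as 299.9994 — metadata checks should
round. Rendering is deterministic: the same tracks, groups and options
yield pixel-identical rasters.

## Synthetic fixture generator

`ngsnap.fixtures` writes a coordinate-sorted, indexed BAM, a GFF3 file and
a tab-separated placement log on one synthetic chromosome (default 10 kb,
50 bp reads, FR proper pairs with a 120 bp inner gap, configurable counts
of single-end reads and pairs per strand plus orphan and secondary decoy
records). Placements are uniform over the chromosome; a fixed seed makes
the output reproducible record-for-record. The log records each fragment's
outer span, aligned blocks and first-mate mapping strand, and is the ground
truth for round-trip tests.

What the generator does *not* emulate: sequencing errors and quality
strings (sequences are uninformative 'A' runs), mismatches, indels and
spliced CIGARs, non-uniform (peaked) coverage, chimeric or multi-mapped
reads, and multiple chromosomes. Tests passing on these fixtures therefore
validate coordinate/flag bookkeeping, strand logic and rendering contracts
— not robustness to messy real-world alignments, which enter only through
pysam's parsing.

Problem sizes used by the test-suite and the acceptance script (hundreds
of reads, windows up to ~10 kb, up to 30 heatmap lanes, 100 randomized
oracle fixtures) were chosen to exercise every code path while keeping a
full run a matter of seconds; coverage computation is linear in fragments
and window length, so nothing changes structurally at realistic scale.

## Known limitations

- BAM with BAI index only; no CRAM, no MAPQ filtering, no on-the-fly
  sorting or indexing.
- Flat same-ID grouping only; no hierarchical parent/child transcript
  reconstruction, no GTF-specific attribute semantics.
- One window per figure; no multi-chromosome composites, no interactive
  zooming.
- Normalization factors are inputs, never estimated.
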