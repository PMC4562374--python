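# ngsnap

Publication-quality, strand-specific snapshots of NGS coverage over a
genomic region of interest.

Genome browsers (IGV, Artemis, GBrowse) are built for interactive
navigation, not for producing an accurate, reproducible figure of many
sequencing libraries side by side. `ngsnap` fills that gap: given one or
more coordinate-sorted, indexed BAM files, GFF annotation and a window
`chrom:start-end`, it computes the per-base coverage signal on each strand
and renders it together with grouped gene models as a high-resolution
(300 dpi by default) tiff, jpeg, png or pdf figure — from a single command
line.

## What it computes

For a window *W* and library *i* with normalization weight *w<sub>i</sub>*,
the signal at base *b* on strand *s* is

> cov<sub>i,s</sub>(b) = w<sub>i</sub> · #{ fragments of library *i* on
> strand *s* whose aligned blocks cover *b* },

optionally displayed as log₂(1 + cov) so that empty positions sit exactly
on the zero baseline. Key semantics:

- **Fragments, not reads.** For paired-end data each proper pair is loaded
  as one single fragment spanning from the leftmost mate start to the
  rightmost mate end, so a pair counts once. Spliced reads contribute
  coverage only over their aligned blocks (no spurious intron signal); the
  unsequenced gap between mates is likewise excluded unless
  `--fill-pair-gap` is given.
- **Strandedness protocols.** `--strandedness {unstranded,forward,reverse}`
  maps a read's mapping strand to its fragment's strand (the dUTP protocol
  is `reverse`; the second mate is flipped automatically).
- **Weights.** Per-library multiplicative factors (e.g. DESeq/edgeR size
  factors or RPM factors), computed externally, rescale raw counts before
  the log transform.
- **Annotation grouping.** GFF2/GFF3 features sharing an ID (exons, UTRs,
  CDS of one transcript) are grouped into a single gene model, drawn with
  per-type shapes (`box`, `rectangle`, `arrow`, `line`) and stacked so
  models never collide.

Three views are available: **classic** (filled areas, one panel per
library, + strand above and − strand below the zero line), **line**
(overlaid curves, one panel, at most 16 libraries) and **heatmap** (one
panel per strand, one lane per library, white→dark-blue color scale, no
library limit).

## Worked example

Every input can be produced by the built-in synthetic fixture generator, so
the example needs no downloads:

```sh
ngsnap fixtures --out-dir fx --single 100 --pairs 50 --seed 42
ngsnap snapshot --window chrS:2001-6000 \
    --bam fx/synthetic.bam:demo:1.0 --layout paired --strandedness forward \
    --gff fx/synthetic.gff3 --mode classic --out demo.png
```

which logs

```
INFO ngsnap.alignment_io: demo: 46 fragments in chrS:2001-6000
INFO ngsnap: library demo: 46 fragments, weight 1 applied
INFO ngsnap.annotation_io: fx/synthetic.gff3: 11 features overlap chrS:2001-6000
INFO ngsnap: annotation: 11 features, 4 groups in 0.00s
INFO ngsnap: render (classic): wrote demo.png in 0.16s
demo.png
```

The 46 fragments are the proper pairs whose aligned blocks overlap the
4 kb window (each pair counted once); the 11 annotation features group into
4 gene models by shared ID; `demo.png` is a 300 dpi figure with one signal
panel (forward-protocol + strand above the axis, − strand below) and one
annotation panel.

The same pipeline is available as a library:

```python
from ngsnap import (GenomicWindow, LibrarySpec, load_fragments,
                    compute_coverage, log2_transform)

window = GenomicWindow("chrS", 2001, 6000)
lib = LibrarySpec(path="fx/synthetic.bam", layout="paired",
                  strandedness="forward", weight=1.0)
track = log2_transform(compute_coverage(load_fragments(lib, window),
                                        window, weight=lib.weight))
```

## Documentation

See `docs/methods.md` for the exact coverage model, the strandedness truth
table, filtering rules, rendering conventions and known limitations.
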