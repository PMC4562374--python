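"""Shared domain types.

All coordinates on a :class:`GenomicWindow` are 1-based inclusive as a user
would type them (the convention of GFF files and genome browsers); every
internal computation uses 0-based half-open intervals, the convention of the
BAM format.  The conversion happens exactly once, when the window is built.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicWindow",
    "Layout",
    "Strandedness",
    "LibrarySpec",
    "AlignedFragment",
    "AnnotationFeature",
    "FeatureStyle",
    "FeatureGroup",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A user-supplied option is outside its allowed vocabulary."""


class Layout(str, enum.Enum):
    """Sequencing layout of a library."""

    SINGLE = "single"
    PAIRED = "paired"


class Strandedness(str, enum.Enum):
    """Library strandedness protocol.

    ``unstranded``
        No strand information (e.g. standard ChIP-seq); all signal is
        collapsed onto the plus strand.
    ``forward``
        The (first-in-pair) read maps to the strand of the original
        fragment, as in ligation-based protocols.
    ``reverse``
        The (first-in-pair) read maps opposite to the fragment's strand,
        as in the common dUTP protocol.
    """

    UNSTRANDED = "unstranded"
    FORWARD = "forward"
    REVERSE = "reverse"

    @classmethod
    def from_token(cls, token: "Strandedness | str") -> "Strandedness":
        if isinstance(token, cls):
            return token
        try:
            return cls(token)
        except ValueError:
            raise ConfigurationError(
                f"unknown strandedness {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class GenomicWindow:
    """The genomic region being snapshot.

    Parameters
    ----------
    chrom
        Reference sequence name.
    start, end
        1-based inclusive bounds, as given by the user.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"window start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"window end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def start0(self) -> int:
        """0-based inclusive start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end."""
        return self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps0(self, start0: int, end0: int) -> bool:
        """Does the 0-based half-open interval ``[start0, end0)`` intersect?"""
        return start0 < self.end0 and end0 > self.start0

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class LibrarySpec:
    """One sequencing library to display.

    ``weight`` is a multiplicative normalization factor (for example a
    DESeq/edgeR size factor or an RPM factor) applied to the library's raw
    coverage; it must be computed externally.
    """

    path: str
    name: str = ""
    layout: Layout = Layout.SINGLE
    strandedness: Strandedness = Strandedness.UNSTRANDED
    weight: float = 1.0
    style: str | None = None

    def __post_init__(self) -> None:
        self.layout = Layout(self.layout)
        self.strandedness = Strandedness.from_token(self.strandedness)
        if not self.name:
            self.name = str(self.path)
        if not self.weight > 0:
            raise ValueError(f"library weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class AlignedFragment:
    """A single sequenced fragment reduced to its aligned footprint.

    For single-end data this is one read; for paired-end data, one proper
    pair merged into a single fragment.  ``blocks`` are the 0-based
    half-open aligned segments that actually receive coverage (splice gaps
    and, by default, the unsequenced gap between mates are excluded);
    ``start``/``end`` give the outer span.
    """

    start: int
    end: int
    strand: str
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"fragment strand must be '+' or '-', got {self.strand!r}")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))


@dataclass(frozen=True)
class AnnotationFeature:
    """One row of a GFF file, kept in its native 1-based inclusive coordinates."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    id: str
    source_line: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"feature end ({self.end}) < start ({self.start}) "
                f"at line {self.source_line}"
            )


#: Shape vocabulary for annotation glyphs.
SHAPES = ("box", "rectangle", "arrow", "line")


@dataclass(frozen=True)
class FeatureStyle:
    """How one feature type is drawn.

    ``box`` is a rectangle with a pointed end showing orientation,
    ``rectangle`` a plain rectangle, ``arrow`` a line with an arrowhead and
    ``line`` a plain line.
    """

    feature_type: str
    shape: str = "box"
    color: str = "0.3"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"unknown shape {self.shape!r} for feature type "
                f"{self.feature_type!r}; expected one of {list(SHAPES)}"
            )


@dataclass
class FeatureGroup:
    """Annotation features sharing one ID, drawn as a single gene model."""

    id: str
    strand: str
    members: list[AnnotationFeature] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive [min start, max end] over all members."""
        return (
            min(m.start for m in self.members),
            max(m.end for m in self.members),
        )


@dataclass
class CoverageTrack:
    """Per-base coverage of one library over the window, split by strand.

    ``plus`` and ``minus`` hold one value per window base (non-negative).
    ``weight_applied`` records the normalization factor already folded into
    the values; ``transformed`` is True once the log2 scale has been applied.
    """

    window: GenomicWindow
    plus: np.ndarray
    minus: np.ndarray
    name: str = ""
    weight_applied: float = 1.0
    transformed: bool = False

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        n = len(self.window)
        if self.plus.shape != (n,) or self.minus.shape != (n,):
            raise ValueError(
                f"track arrays must have window length {n}, got "
                f"{self.plus.shape} / {self.minus.shape}"
            )
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("coverage values must be non-negative")


def positions(window: GenomicWindow) -> np.ndarray:
    """Genomic x-coordinates (1-based) for each base of the window."""
    return np.arange(window.start, window.end + 1)
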