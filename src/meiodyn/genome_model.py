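"""Genome layout, genomic intervals and BED-family I/O.

All coordinates are 0-based half-open (BED convention) internally.  Readers
for 1-based formats (e.g. cytosine reports) convert at the boundary.  A
:class:`GenomeLayout` records chromosome lengths and the autosome/sex split;
every interval container validates against it so downstream arithmetic can
assume ``0 <= start < end <= length``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "STAGES",
    "MARKS",
    "GenomeLayout",
    "GenomicInterval",
    "PeakSet",
    "StageOrder",
    "ExtendResult",
    "width",
    "overlaps",
    "extend",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]

#: Spermatogenic stage labels, earliest first: undifferentiated spermatogonia,
#: type A1 / type B spermatogonia, mid-preleptotene, leptotene, early/mid/late
#: zygotene, early 1- and early 2-pachytene, mid-pachytene, diplotene.
STAGES: tuple[str, ...] = (
    "Undiff", "A1", "B", "mpL", "L", "eZ", "mZ", "lZ", "e1P", "e2P", "mP", "D",
)

#: Histone marks handled by the pipeline.
MARKS: tuple[str, ...] = (
    "H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K9me2", "H3K9me3", "H3K27me3",
)


class BedParseError(ValueError):
    """Malformed BED/narrowPeak line (carries the 1-based line number)."""


def _looks_like_sex_chrom(name: str) -> bool:
    base = name.removeprefix("chr").upper()
    return base in {"X", "Y", "M", "MT"}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length (bp), with an autosome flag per name.

    Sex chromosomes (and mitochondria) are kept in the model; analyses that
    exclude them do so with :meth:`autosomes` at pipeline level.
    """

    lengths: dict[str, int]
    autosome: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {n}")
        auto = dict(self.autosome)
        for name in self.lengths:
            auto.setdefault(name, not _looks_like_sex_chrom(name))
        object.__setattr__(self, "autosome", auto)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.lengths if self.autosome[c])

    def total_bp(self, autosomes_only: bool = False) -> int:
        names = self.autosomes() if autosomes_only else self.chroms
        return sum(self.lengths[c] for c in names)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome.

    Ordering is (chrom, start, end) so sorting a list of intervals yields
    coordinate order.
    """

    chrom: str
    start: int
    end: int
    name: str | None = dataclasses.field(default=None, compare=False)
    score: float | None = dataclasses.field(default=None, compare=False)
    pvalue: float | None = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def validate(self, layout: GenomeLayout) -> "GenomicInterval":
        if self.chrom not in layout:
            raise ValueError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout[self.chrom]}"
            )
        return self

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def width(interval: GenomicInterval) -> int:
    """Peak width: end coordinate minus start coordinate (bp)."""
    return interval.end - interval.start


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases (half-open).

    Abutting intervals share zero bases and do not overlap.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


class ExtendResult(NamedTuple):
    interval: GenomicInterval
    clipped: bool


def extend(
    interval: GenomicInterval, left_bp: int, right_bp: int, layout: GenomeLayout
) -> ExtendResult:
    """Widen an interval by ``left_bp``/``right_bp``, clipping at chromosome ends.

    The ``clipped`` flag is set only when truncation actually occurred (landing
    exactly on a boundary is not clipping).
    """
    if left_bp < 0 or right_bp < 0:
        raise ValueError("extension amounts must be non-negative")
    chrom_len = layout[interval.chrom]
    start = interval.start - left_bp
    end = interval.end + right_bp
    clipped = start < 0 or end > chrom_len
    return ExtendResult(
        GenomicInterval(
            interval.chrom, max(start, 0), min(end, chrom_len),
            name=interval.name, score=interval.score, pvalue=interval.pvalue,
        ),
        clipped,
    )


class PeakSet:
    """Coordinate-sorted set of intervals for one mark at one stage.

    ``mark`` and ``stage`` are optional so the same container serves DSB
    hotspots, NDRs and other generic feature sets.  Duplicate identical
    coordinates are dropped on construction.  Per-chromosome start/end arrays
    are cached for fast overlap queries.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        layout: GenomeLayout,
        mark: str | None = None,
        stage: str | None = None,
    ) -> None:
        if mark is not None and mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        if stage is not None and stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        seen: set[tuple[str, int, int]] = set()
        kept: list[GenomicInterval] = []
        for iv in intervals:
            iv.validate(layout)
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                continue
            seen.add(key)
            kept.append(iv)
        kept.sort()
        self.intervals: tuple[GenomicInterval, ...] = tuple(kept)
        self.layout = layout
        self.mark = mark
        self.stage = stage
        tmp: dict[str, list[list[int]]] = {}
        for i, iv in enumerate(kept):
            tmp.setdefault(iv.chrom, [[], [], []])
            tmp[iv.chrom][0].append(iv.start)
            tmp[iv.chrom][1].append(iv.end)
            tmp[iv.chrom][2].append(i)
        self._by_chrom = {
            c: (np.asarray(s), np.asarray(e), np.asarray(idx))
            for c, (s, e, idx) in tmp.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, original indices) for one chromosome, start-sorted."""
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        empty = np.asarray([], dtype=int)
        return empty, empty, empty

    def overlapping_indices(
        self, query: GenomicInterval, min_bp: int = 1
    ) -> np.ndarray:
        """Indices (into this set) of intervals overlapping ``query`` >= min_bp."""
        if min_bp < 1:
            raise ValueError(f"min_bp must be >= 1, got {min_bp}")
        starts, ends, idx = self.chrom_arrays(query.chrom)
        if len(starts) == 0:
            return np.asarray([], dtype=int)
        shared = np.minimum(ends, query.end) - np.maximum(starts, query.start)
        return idx[shared >= min_bp]

    def overlaps_any(self, query: GenomicInterval, min_bp: int = 1) -> bool:
        return len(self.overlapping_indices(query, min_bp=min_bp)) > 0

    def presence_of(self, queries: Sequence[GenomicInterval], min_bp: int = 1) -> np.ndarray:
        """Boolean vector: does each query overlap any member of this set."""
        return np.asarray(
            [self.overlaps_any(q, min_bp=min_bp) for q in queries], dtype=bool
        )

    def subset(self, keep: Sequence[int] | np.ndarray) -> "PeakSet":
        ivs = [self.intervals[i] for i in keep]
        return PeakSet(ivs, self.layout, mark=self.mark, stage=self.stage)

    def restrict_to_autosomes(self) -> "PeakSet":
        auto = set(self.layout.autosomes())
        return PeakSet(
            [iv for iv in self.intervals if iv.chrom in auto],
            self.layout, mark=self.mark, stage=self.stage,
        )


@dataclass(frozen=True)
class StageOrder:
    """Total order over stage labels, earliest first."""

    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")

    def index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ValueError(f"stage {stage!r} not in order {self.stages}") from None

    def before(self, stage: str) -> tuple[str, ...]:
        """All stages strictly earlier than ``stage``."""
        return self.stages[: self.index(stage)]

    def is_earlier(self, a: str, b: str) -> bool:
        return self.index(a) < self.index(b)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column ``<chrom>\\t<length>`` text file -> GenomeLayout."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected two columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from None
    return GenomeLayout(lengths)


def _parse_optional_float(tok: str) -> float | None:
    if tok in {".", ""}:
        return None
    return float(tok)


def read_bed(
    path: str | Path,
    layout: GenomeLayout,
    mark: str | None = None,
    stage: str | None = None,
    one_based: bool = False,
) -> PeakSet:
    """Read BED3+/BED6/narrowPeak-like tab-separated peaks into a sorted PeakSet.

    narrowPeak 10-column rows populate ``score`` (column 7, signalValue) and
    ``pvalue`` (column 8, -log10 transformed back to a probability).  Set
    ``one_based=True`` for 1-based fully-closed inputs; coordinates are then
    shifted to the internal 0-based half-open convention.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if one_based:
                start -= 1
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score: float | None = None
            pvalue: float | None = None
            if len(parts) >= 10:  # narrowPeak: signalValue col 7, -log10 p col 8
                score = _parse_optional_float(parts[6])
                neglog = _parse_optional_float(parts[7])
                if neglog is not None and neglog >= 0:
                    pvalue = 10.0 ** (-neglog)
            elif len(parts) >= 5:
                score = _parse_optional_float(parts[4])
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if chrom not in layout:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in layout"
                )
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, pvalue=pvalue)
            )
    return PeakSet(intervals, layout, mark=mark, stage=stage)


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as narrowPeak-style 10-column rows (lossless round-trip).

    Missing name/score/pvalue are written as ``.``/0; the p-value column holds
    -log10(p) per the narrowPeak convention.
    """
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:.17g}" if iv.score is not None else "."
            if iv.pvalue is not None and iv.pvalue > 0:
                neglog = f"{-np.log10(iv.pvalue):.17g}"
            else:
                neglog = "-1"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t{score}\t{neglog}\t-1\t-1\n"
            )
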