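"""Genomic coordinate types.

All coordinates in this package are 0-based, half-open ``[start, end)`` —
the BED convention. Two intervals overlap iff
``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PipelineError

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PipelineError(
                "bed-empty-interval",
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}",
            )
        if self.strand not in VALID_STRANDS:
            raise PipelineError("bad-strand", f"strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise PipelineError("different-chrom", "distance across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end + 1, other.start - self.end + 1, 0)

    def expanded(self, pad: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS and body interval.

    The TSS is a length-1 interval at the 5' end of the body: ``body.start``
    on the + strand, ``body.end - 1`` on the - strand.
    """

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise PipelineError("bad-strand", f"gene strand {self.strand!r}")

    @property
    def tss(self) -> GenomicInterval:
        pos = self.body.start if self.strand == "+" else self.body.end - 1
        return GenomicInterval(self.body.chrom, pos, pos + 1, self.strand)

    def tss_window(self, half_width: int) -> GenomicInterval:
        pos = self.tss.start
        return GenomicInterval(self.body.chrom, max(0, pos - half_width), pos + half_width + 1)


@dataclass
class SignalTrack:
    """Per-interval constant signal (a bedGraph in memory).

    Intervals must be non-overlapping; uncovered bases read as 0.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.intervals) != len(self.values):
            raise PipelineError("track-shape", "intervals/values length mismatch")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.values = [float(self.values[i]) for i in order]
        prev = None
        for iv, v in zip(self.intervals, self.values):
            if not (v == v and abs(v) != float("inf")):
                raise PipelineError("track-value", "non-finite signal value")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise PipelineError("track-overlap", f"overlapping intervals at {iv}")
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def _index(self):
        # lazy per-chrom numpy arrays (starts, ends, values) for fast queries
        if not hasattr(self, "_idx") or self._idx is None:
            import numpy as np

            idx: dict[str, tuple] = {}
            by_chrom: dict[str, list[int]] = {}
            for i, iv in enumerate(self.intervals):
                by_chrom.setdefault(iv.chrom, []).append(i)
            for chrom, rows in by_chrom.items():
                idx[chrom] = (
                    np.array([self.intervals[i].start for i in rows]),
                    np.array([self.intervals[i].end for i in rows]),
                    np.array([self.values[i] for i in rows]),
                )
            object.__setattr__(self, "_idx", idx)
        return self._idx

    def mean_over(self, region: GenomicInterval) -> float:
        """Length-weighted mean over `region`; uncovered bases count as 0."""
        import numpy as np

        idx = self._index().get(region.chrom)
        if idx is None:
            return 0.0
        starts, ends, values = idx
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        total = float((values[lo:hi] * np.maximum(ov, 0)).sum())
        return total / len(region)
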