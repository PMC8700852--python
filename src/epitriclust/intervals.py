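"""Genomic interval and signal-track containers.

Coordinates are BED-style 0-based half-open everywhere in this package;
interval length is always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally named and stranded.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates (bp); ``0 <= start < end``.
    name : str
        Identifier (gene / promoter id). May be empty for anonymous
        sub-intervals such as bins.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) "
                f"for {self.name or self.chrom!r}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length in bp of the overlap with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class SignalTrack:
    """Binned genomic signal for one (sample group, epigenetic mark) pair.

    ``records`` is a list of ``(GenomicInterval, value)`` with non-negative
    values, sorted by (chrom, start) and non-overlapping within the track.
    """

    group: str
    mark: str
    records: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev: GenomicInterval | None = None
        for iv, value in self.records:
            if value < 0:
                raise ValueError(
                    f"negative signal value {value} at "
                    f"{iv.chrom}:{iv.start}-{iv.end} in track "
                    f"({self.group}, {self.mark})"
                )
            if prev is not None:
                if (iv.chrom, iv.start) < (prev.chrom, prev.start):
                    raise ValueError(
                        "track records not sorted by (chrom, start): "
                        f"{prev.chrom}:{prev.start} followed by {iv.chrom}:{iv.start}"
                    )
                if iv.chrom == prev.chrom and iv.start < prev.end:
                    raise ValueError(
                        "overlapping records in track "
                        f"({self.group}, {self.mark}): "
                        f"{prev.chrom}:{prev.start}-{prev.end} overlaps "
                        f"{iv.chrom}:{iv.start}-{iv.end}"
                    )
            prev = iv

    @property
    def total_signal(self) -> float:
        """Total signal mass of the track (sum of record values)."""
        return float(sum(v for _, v in self.records))
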