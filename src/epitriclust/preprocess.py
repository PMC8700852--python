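"""Phase 1: promoter binning, bin counting, depth normalization, tensor assembly.

Each epigenetic mark yields a 3-D tensor of normalized signal indexed
(group, gene, bin), where groups are the sample classes (e.g. cancer
types), genes come from the promoter list, and bins are fixed-count
sub-intervals of each promoter, ordered promoter-proximal first
(strand-aware).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, SignalTrack

#: Default number of bins each promoter is partitioned into.
DEFAULT_N_BINS = 10

#: Default common depth target for linear normalization (counts-per-million
#: analogue: every group's track is scaled so its total mass equals this).
DEFAULT_TARGET_TOTAL = 1e6


@dataclass
class MarkTensor:
    """Normalized signal tensor for one epigenetic mark.

    ``values`` has shape ``(len(groups), len(genes), n_bins)`` with
    non-negative, finite entries.
    """

    mark: str
    groups: list[str]
    genes: list[str]
    n_bins: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.groups), len(self.genes), self.n_bins)
        if self.values.shape != expected:
            raise ValueError(
                f"tensor shape {self.values.shape} != expected {expected}"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2 for correlation to be defined")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("tensor contains negative values")

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def profile(self, group: str, gene: str) -> np.ndarray:
        """Bin profile for one (group, gene) pair."""
        return self.values[self.group_index(group), self.gene_index(gene)]


def bin_interval(region: GenomicInterval, n_bins: int) -> list[GenomicInterval]:
    """Partition ``region`` into ``n_bins`` contiguous sub-intervals.

    Bin lengths differ by at most 1 bp (the remainder goes to the earliest
    genomic bins).  The returned list is ordered promoter-proximal first:
    genomic order for '+' or unstranded regions, reversed for '-'.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    length = len(region)
    if length < n_bins:
        raise ValueError(
            f"region {region.name or region.chrom!r} has length {length} "
            f"< n_bins={n_bins}"
        )
    base, rem = divmod(length, n_bins)
    bins: list[GenomicInterval] = []
    pos = region.start
    for b in range(n_bins):
        width = base + (1 if b < rem else 0)
        bins.append(
            GenomicInterval(region.chrom, pos, pos + width, strand=region.strand)
        )
        pos += width
    assert pos == region.end
    if region.strand == "-":
        bins.reverse()
    return bins


def count_in_bins(track: SignalTrack, bins: list[GenomicInterval]) -> np.ndarray:
    """Signal mass per bin, attributing records fractionally by overlap.

    Each record of value v contributes ``v * overlap / record_length`` to
    every bin it overlaps, so total mass is conserved: a record fully
    contained in the binned region contributes exactly v in total.
    """
    out = np.zeros(len(bins), dtype=float)
    if not track.records or not bins:
        return out
    lo = min(b.start for b in bins)
    hi = max(b.end for b in bins)
    chrom = bins[0].chrom
    # records are sorted; restrict the scan window by binary search
    keys = [(iv.chrom, iv.start) for iv, _ in track.records]
    i = bisect_left(keys, (chrom, 0))
    while i < len(track.records):
        iv, value = track.records[i]
        if iv.chrom != chrom or iv.start >= hi:
            break
        if iv.end > lo:
            rlen = len(iv)
            for b, biv in enumerate(bins):
                ov = biv.overlap_length(iv)
                if ov:
                    out[b] += value * ov / rlen
        i += 1
    return out


def normalize_linear(
    tensor_slice: np.ndarray, library_total: float, target_total: float
) -> np.ndarray:
    """Linear depth scaling: multiply every value by target/library.

    Relative profile shapes are unchanged; identity when the totals match.
    """
    if library_total <= 0:
        raise ValueError(f"library_total must be > 0, got {library_total}")
    if target_total <= 0:
        raise ValueError(f"target_total must be > 0, got {target_total}")
    return np.asarray(tensor_slice, dtype=float) * (target_total / library_total)


def build_mark_tensor(
    tracks: list[SignalTrack],
    promoters: list[GenomicInterval],
    n_bins: int = DEFAULT_N_BINS,
    target_total: float = DEFAULT_TARGET_TOTAL,
    library_from_promoters: bool = False,
) -> MarkTensor:
    """Assemble the per-mark tensor (groups x genes x bins) from raw tracks.

    One track per group, all for the same mark and sharing the promoter
    list.  Gene order equals promoter file order.  Each group's slice is
    depth-normalized to ``target_total``; the library size is the group's
    full-track mass by default, or the promoter-restricted mass when
    ``library_from_promoters`` is set.  A group with an empty track yields
    an all-zero slice.
    """
    if not tracks:
        raise ValueError("no tracks given")
    marks = {t.mark for t in tracks}
    if len(marks) > 1:
        raise ValueError(f"tracks span multiple marks: {sorted(marks)}")
    groups = [t.group for t in tracks]
    if len(set(groups)) != len(groups):
        raise ValueError(f"duplicate group labels among tracks: {groups}")
    names = [p.name for p in promoters]
    if len(set(names)) != len(names):
        raise ValueError("duplicate promoter names")
    if any(not n for n in names):
        raise ValueError("promoters must be named")

    bins_per_gene = []
    for p in promoters:
        try:
            bins_per_gene.append(bin_interval(p, n_bins))
        except ValueError as exc:
            raise ValueError(f"promoter {p.name!r}: {exc}") from exc

    raw = np.zeros((len(tracks), len(promoters), n_bins), dtype=float)
    for gi, track in enumerate(tracks):
        for ni, bins in enumerate(bins_per_gene):
            raw[gi, ni] = count_in_bins(track, bins)

    values = np.zeros_like(raw)
    for gi, track in enumerate(tracks):
        lib = raw[gi].sum() if library_from_promoters else track.total_signal
        if lib > 0:
            values[gi] = normalize_linear(raw[gi], lib, target_total)
        # empty track (or no promoter overlap): slice stays zero

    return MarkTensor(
        mark=tracks[0].mark,
        groups=groups,
        genes=names,
        n_bins=n_bins,
        values=values,
    )
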