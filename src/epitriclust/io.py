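"""Readers and writers for every on-disk representation the pipeline touches.

Formats: BED4/BED6 for promoter lists, 4-column bedGraph for signal,
long-format TSV for tensors (columns mark, group, gene, bin_index, value)
and transactions (mark, gene, item), JSON for cluster reports and planted
ground truth.  All round-trip: read(write(x)) == x.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .bicluster import Bicluster
from .coherence import Transaction, make_item, pearson
from .intervals import GenomicInterval, SignalTrack
from .preprocess import MarkTensor
from .synthetic import PlantedBlock
from .tricluster import Tricluster

Cluster = Union[Bicluster, Tricluster]

TENSOR_COLUMNS = ["mark", "group", "gene", "bin_index", "value"]
TRANSACTION_COLUMNS = ["mark", "gene", "item"]


# ---------------------------------------------------------------- intervals


def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED4/BED6 file into named intervals (file order kept)."""
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            if not name:
                raise ValueError(f"{path}:{lineno}: empty interval name")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_bedgraph(path, group: str, mark: str) -> SignalTrack:
    """Parse a 4-column bedGraph into a sorted, validated SignalTrack."""
    records: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable fields") from exc
            if value < 0:
                raise ValueError(
                    f"{path}:{lineno}: negative signal value {value}"
                )
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append((iv, value))
    records.sort(key=lambda rv: (rv[0].chrom, rv[0].start))
    try:
        return SignalTrack(group=group, mark=mark, records=records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------ tensors


def write_tensors(tensors: Iterable[MarkTensor] | MarkTensor, path) -> None:
    """Write one or more tensors as long-format TSV."""
    if isinstance(tensors, MarkTensor):
        tensors = [tensors]
    frames = []
    for t in tensors:
        n_g, n_n, n_b = t.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "mark": np.repeat(t.mark, n_g * n_n * n_b),
                    "group": np.repeat(t.groups, n_n * n_b),
                    "gene": np.tile(np.repeat(t.genes, n_b), n_g),
                    "bin_index": np.tile(np.arange(n_b), n_g * n_n),
                    "value": t.values.reshape(-1),
                }
            )
        )
    # %.17g round-trips every IEEE double exactly
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_tensors(path) -> dict[str, MarkTensor]:
    """Read a long-format tensor TSV back into per-mark tensors.

    Group and gene orders follow first appearance in the file, so a
    write/read round trip preserves axis order and values exactly.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"mark": str, "group": str, "gene": str},
        float_precision="round_trip",
    )
    missing = set(TENSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing tensor columns {sorted(missing)}")
    tensors: dict[str, MarkTensor] = {}
    for mark, sub in df.groupby("mark", sort=False):
        groups = list(dict.fromkeys(sub["group"]))
        genes = list(dict.fromkeys(sub["gene"]))
        n_bins = int(sub["bin_index"].max()) + 1
        values = np.zeros((len(groups), len(genes), n_bins), dtype=float)
        gi = {g: i for i, g in enumerate(groups)}
        ni = {n: i for i, n in enumerate(genes)}
        values[
            sub["group"].map(gi).to_numpy(),
            sub["gene"].map(ni).to_numpy(),
            sub["bin_index"].to_numpy(),
        ] = sub["value"].to_numpy()
        tensors[mark] = MarkTensor(
            mark=mark, groups=groups, genes=genes, n_bins=n_bins, values=values
        )
    return tensors


# ------------------------------------------------------------- transactions


def write_transactions(transactions: Sequence[Transaction], path) -> None:
    """Transactions as TSV, one row per item; item serialized "A|B".

    A gene whose transaction is empty still gets one row with an empty
    item field, so the studied-gene roster (the support denominator)
    survives the round trip.
    """
    rows = []
    for t in transactions:
        if t.items:
            for a, b in sorted(t.items):
                rows.append((t.mark, t.gene, f"{a}|{b}"))
        else:
            rows.append((t.mark, t.gene, ""))
    pd.DataFrame(rows, columns=TRANSACTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_transactions(path) -> list[Transaction]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TRANSACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing transaction columns {sorted(missing)}")
    items: dict[tuple[str, str], set] = {}
    order: list[tuple[str, str]] = []
    for mark, gene, item in df.itertuples(index=False):
        key = (mark, gene)
        if key not in items:
            items[key] = set()
            order.append(key)
        if item:
            a, _, b = item.partition("|")
            if not b:
                raise ValueError(f"{path}: malformed item {item!r}")
            items[key].add(make_item(a, b))
    return [
        Transaction(gene=gene, mark=mark, items=frozenset(items[(mark, gene)]))
        for mark, gene in order
    ]


# ----------------------------------------------------------------- clusters


def _mean_correlation(
    marks: Iterable[str],
    groups: Iterable[str],
    genes: Iterable[str],
    tensors: dict[str, MarkTensor],
) -> float | None:
    from itertools import combinations

    rs = []
    for mark in sorted(marks):
        tensor = tensors[mark]
        for gene in sorted(genes):
            gi = tensor.gene_index(gene)
            for a, b in combinations(sorted(groups), 2):
                r = pearson(
                    tensor.values[tensor.group_index(a), gi],
                    tensor.values[tensor.group_index(b), gi],
                )
                if r is not None:
                    rs.append(r)
    return float(np.mean(rs)) if rs else None


def write_clusters(
    clusters: Sequence[Cluster],
    path,
    tensors: dict[str, MarkTensor] | None = None,
) -> None:
    """Cluster report as a JSON array of 5-key objects.

    Keys: marks, groups, genes (sorted lists), support, and
    mean_correlation — the mean of all within-cluster pairwise profile
    correlations, computed when ``tensors`` is given, else null.
    """
    payload = []
    for c in clusters:
        marks = sorted(c.marks) if isinstance(c, Tricluster) else [c.mark]
        obj = {
            "marks": marks,
            "groups": sorted(c.groups),
            "genes": sorted(c.genes),
            "support": c.support,
            "mean_correlation": (
                _mean_correlation(marks, c.groups, c.genes, tensors)
                if tensors is not None
                else None
            ),
        }
        payload.append(obj)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_clusters(path) -> list[Cluster]:
    """Read a cluster report; one mark -> Bicluster, several -> Tricluster."""
    payload = json.loads(Path(path).read_text())
    clusters: list[Cluster] = []
    for obj in payload:
        marks = obj["marks"]
        if len(marks) == 1:
            clusters.append(
                Bicluster(
                    mark=marks[0],
                    groups=frozenset(obj["groups"]),
                    genes=frozenset(obj["genes"]),
                )
            )
        else:
            clusters.append(
                Tricluster(
                    marks=frozenset(marks),
                    groups=frozenset(obj["groups"]),
                    genes=frozenset(obj["genes"]),
                )
            )
    return clusters


# -------------------------------------------------------------- truth blocks


def write_truth(blocks: Sequence[PlantedBlock], path) -> None:
    payload = [
        {
            "marks": sorted(b.marks),
            "groups": sorted(b.groups),
            "genes": sorted(b.genes),
        }
        for b in blocks
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> list[PlantedBlock]:
    payload = json.loads(Path(path).read_text())
    return [
        PlantedBlock(
            marks=frozenset(obj["marks"]),
            groups=frozenset(obj["groups"]),
            genes=frozenset(obj["genes"]),
        )
        for obj in payload
    ]
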