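"""Phase 2 front end: per-gene pairwise coherence and transactions.

For each gene under one mark, every unordered pair of sample groups whose
bin-profiles correlate at or above the threshold theta becomes an "item";
the set of such pairs is the gene's transaction, the unit later counted
for support by the frequent-pattern miner.

The threshold is applied as a closed bound (r >= theta).  Profiles with
zero variance carry no trend evidence, so any pair involving one is
excluded rather than treated as coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import MarkTensor

#: Default coherence threshold.
DEFAULT_THETA = 0.65
#: Alternate, stricter preset.
STRICT_THETA = 0.72

#: A transaction item: an unordered group pair, stored label-sorted.
Item = tuple[str, str]


def make_item(a: str, b: str) -> Item:
    """Canonical (sorted) form of an unordered group-pair item."""
    if a == b:
        raise ValueError(f"item endpoints must differ, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Transaction:
    """Coherent group pairs for one gene under one mark."""

    gene: str
    mark: str
    items: frozenset[Item] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for a, b in self.items:
            if a >= b:
                raise ValueError(f"item ({a!r}, {b!r}) not in canonical order")


def pearson(x, y) -> float | None:
    """Product-moment correlation of two equal-length vectors.

    Returns ``None`` (the undefined flag) when either vector has zero
    variance.  The result is clipped to [-1, 1]; bitwise-identical inputs
    yield exactly 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("pearson expects 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        return None
    # sqrt(sxx * syy) keeps identical inputs at exactly 1.0
    r = float(xd @ yd) / float(np.sqrt(sxx * syy))
    return float(min(1.0, max(-1.0, r)))


def pairwise_correlations(profiles: np.ndarray) -> np.ndarray:
    """Correlation matrix across the rows of a (groups x bins) array.

    Entries involving a zero-variance row are NaN.  Vectorized equivalent
    of calling :func:`pearson` on every row pair.
    """
    profiles = np.asarray(profiles, dtype=float)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    ss = np.einsum("ib,ib->i", centered, centered)
    num = centered @ centered.T
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    zero = ss == 0
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    return np.clip(corr, -1.0, 1.0)


def gene_transaction(
    tensor: MarkTensor, gene_index: int, theta: float = DEFAULT_THETA
) -> Transaction:
    """Transaction for one gene: all group pairs with r >= theta."""
    _check_theta(theta)
    if not 0 <= gene_index < len(tensor.genes):
        raise IndexError(f"gene_index {gene_index} out of range")
    profiles = tensor.values[:, gene_index, :]
    corr = pairwise_correlations(profiles)
    items = set()
    n = len(tensor.groups)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if not np.isnan(r) and r >= theta:
                items.add(make_item(tensor.groups[i], tensor.groups[j]))
    return Transaction(
        gene=tensor.genes[gene_index], mark=tensor.mark, items=frozenset(items)
    )


def build_transactions(
    tensor: MarkTensor, theta: float = DEFAULT_THETA
) -> list[Transaction]:
    """One transaction per gene, in tensor gene order. Deterministic."""
    _check_theta(theta)
    out: list[Transaction] = []
    n_groups = len(tensor.groups)
    # all-gene vectorization: centered profiles (groups, genes, bins)
    centered = tensor.values - tensor.values.mean(axis=2, keepdims=True)
    ss = np.einsum("gnb,gnb->gn", centered, centered)  # (groups, genes)
    num = np.einsum("anb,cnb->nac", centered, centered)  # (genes, g, g)
    denom = np.sqrt(ss.T[:, :, None] * ss.T[:, None, :])
    pairs = [
        (i, j, make_item(tensor.groups[i], tensor.groups[j]))
        for i in range(n_groups)
        for j in range(i + 1, n_groups)
    ]
    for n, gene in enumerate(tensor.genes):
        items = set()
        for i, j, item in pairs:
            d = denom[n, i, j]
            if d > 0 and min(1.0, num[n, i, j] / d) >= theta:
                items.add(item)
        out.append(Transaction(gene=gene, mark=tensor.mark, items=frozenset(items)))
    return out


def _check_theta(theta: float) -> None:
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
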