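"""Phase 2 back end: frequent group-pair itemsets to per-mark biclusters.

A frequent itemset over group-pair items is accepted only when its pairs
form a complete graph (clique) over the groups they touch: pairwise
correlation is not transitive, so all-pairs coherence is required before
the pairs can be read as one coherent group set.  Clique-consistent
itemsets become (group set x gene set) biclusters; dominated ones
(superset groups AND superset genes elsewhere) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .coherence import (
    DEFAULT_THETA,
    Item,
    Transaction,
    build_transactions,
    make_item,
)
from .fpgrowth import (
    FrequentItemSet,
    fpgrowth,
    minimum_support_from_fraction,
)
from .preprocess import MarkTensor

#: Default minimum support as a fraction of studied genes.
DEFAULT_MIN_SUPPORT_FRACTION = 0.10


@dataclass(frozen=True)
class Bicluster:
    """(group set x gene set) for one mark, all group pairs coherent."""

    mark: str
    groups: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("bicluster needs at least 2 groups")
        if not self.genes:
            raise ValueError("bicluster needs a non-empty gene set")

    @property
    def support(self) -> int:
        return len(self.genes)


def itemset_to_group_set(items: frozenset[Item]) -> frozenset[str] | None:
    """Groups covered by a pair-itemset, or None unless it is a clique.

    Accepts iff the items are exactly all C(|V|, 2) pairs over the union V
    of their endpoints (single edges are 2-cliques).
    """
    if not items:
        raise ValueError("empty itemset")
    vertices = frozenset(v for pair in items for v in pair)
    required = {make_item(a, b) for a, b in combinations(sorted(vertices), 2)}
    return vertices if set(items) == required else None


def extract_biclusters(
    frequent: list[FrequentItemSet], min_support: int
) -> list[Bicluster]:
    """Clique-consistent frequent itemsets as maximal biclusters.

    The mark label is taken from the caller's context via
    :func:`mine_mark_biclusters`; here itemsets are assumed to belong to a
    single mark and the returned biclusters carry an empty mark when the
    itemsets do not know theirs.  Non-maximal biclusters (dominated in
    both groups and genes by another) are removed.
    """
    return _extract(frequent, min_support, mark="")


def _extract(
    frequent: list[FrequentItemSet], min_support: int, mark: str
) -> list[Bicluster]:
    candidates: list[Bicluster] = []
    for fis in frequent:
        if fis.support < min_support:
            continue
        groups = itemset_to_group_set(fis.items)
        if groups is None:
            continue
        candidates.append(
            Bicluster(mark=mark, groups=groups, genes=frozenset(fis.supporting_ids))
        )
    kept = _drop_dominated(candidates)
    kept.sort(
        key=lambda b: (
            -len(b.groups),
            -b.support,
            tuple(sorted(b.groups)),
            tuple(sorted(b.genes)),
        )
    )
    return kept


def _drop_dominated(candidates: list[Bicluster]) -> list[Bicluster]:
    # a bicluster dies only if another has superset groups AND superset
    # genes (and is not an exact duplicate); incomparable ones all survive
    unique = list({(b.groups, b.genes): b for b in candidates}.values())
    kept = []
    for b in unique:
        dominated = any(
            o is not b
            and o.groups >= b.groups
            and o.genes >= b.genes
            and (o.groups, o.genes) != (b.groups, b.genes)
            for o in unique
        )
        if not dominated:
            kept.append(b)
    return kept


def mine_mark_biclusters(
    transactions: list[Transaction],
    min_support: int,
) -> list[Bicluster]:
    """Full Phase-2 back end for one mark's transactions."""
    if not transactions:
        return []
    marks = {t.mark for t in transactions}
    if len(marks) > 1:
        raise ValueError(f"transactions span multiple marks: {sorted(marks)}")
    frequent = fpgrowth(
        [t.items for t in transactions],
        min_support,
        ids=[t.gene for t in transactions],
    )
    return _extract(frequent, min_support, mark=marks.pop())


def biclusters_from_tensor(
    tensor: MarkTensor,
    theta: float = DEFAULT_THETA,
    min_support_fraction: float = DEFAULT_MIN_SUPPORT_FRACTION,
) -> list[Bicluster]:
    """Tensor straight to biclusters (transactions built internally)."""
    min_support = minimum_support_from_fraction(
        len(tensor.genes), min_support_fraction
    )
    return mine_mark_biclusters(build_transactions(tensor, theta), min_support)


def candidate_biclusters(
    transactions: list[Transaction], min_support: int
) -> list[Bicluster]:
    """Clique-consistent frequent patterns before maximality pruning.

    Because raising theta only shrinks transactions, the set of these
    candidates at a higher threshold is a subset of the set at a lower
    one — unlike the maximal set, whose size can fluctuate when a
    dominating cluster drops below support and releases the patterns it
    shadowed.
    """
    if not transactions:
        return []
    marks = {t.mark for t in transactions}
    if len(marks) > 1:
        raise ValueError(f"transactions span multiple marks: {sorted(marks)}")
    mark = marks.pop()
    frequent = fpgrowth(
        [t.items for t in transactions],
        min_support,
        ids=[t.gene for t in transactions],
    )
    out = []
    for fis in frequent:
        if fis.support < min_support:
            continue
        groups = itemset_to_group_set(fis.items)
        if groups is not None:
            out.append(
                Bicluster(
                    mark=mark, groups=groups, genes=frozenset(fis.supporting_ids)
                )
            )
    return out


def sweep_thresholds(
    tensor: MarkTensor,
    thetas: list[float],
    min_support: int,
) -> dict[float, int]:
    """Coherent-pattern count per threshold (the threshold-sweep curve).

    Counts clique-consistent frequent patterns (pre-maximality), which is
    provably non-increasing in theta on any fixed tensor.
    """
    if list(thetas) != sorted(thetas):
        raise ValueError("thetas must be sorted ascending")
    counts: dict[float, int] = {}
    for theta in thetas:
        transactions = build_transactions(tensor, theta)
        counts[theta] = len(candidate_biclusters(transactions, min_support))
    return counts


def verify_bicluster(
    b: Bicluster, tensor: MarkTensor, theta: float
) -> list[tuple[str, Item, float | None]]:
    """Direct recomputation check, independent of the mining path.

    Returns the list of violations (gene, group pair, correlation): empty
    means every supporting gene has all within-group pairwise correlations
    at or above theta.
    """
    from .coherence import pearson  # local to avoid a tight import surface

    failures: list[tuple[str, Item, float | None]] = []
    for gene in sorted(b.genes):
        gi = tensor.gene_index(gene)
        for a, c in combinations(sorted(b.groups), 2):
            r = pearson(
                tensor.values[tensor.group_index(a), gi],
                tensor.values[tensor.group_index(c), gi],
            )
            if r is None or r < theta:
                failures.append((gene, make_item(a, c), r))
    return failures
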