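"""Frequent-pattern-growth mining, from scratch.

Textbook FP-growth: items below minimum support are dropped, each
transaction is inserted into a prefix tree in descending global-frequency
order (ties broken lexicographically), and frequent itemsets are mined
recursively from conditional pattern bases, suffix by suffix.  A
brute-force subset-enumeration oracle is provided for testing.

Items may be any hashable, orderable labels; in this package they are
group-pair tuples.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Sequence

Itemset = frozenset

_BRUTE_FORCE_MAX_ITEMS = 20


class FPNode:
    """One node of an FP-tree: an item with a count on a prefix path."""

    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item: Hashable, parent: "FPNode | None") -> None:
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[Hashable, FPNode] = {}
        self.link: FPNode | None = None  # next node holding the same item


@dataclass
class FPTree:
    """FP-tree with header table and the (id, itemset) transactions it holds.

    The header maps item -> chain head, ordered by descending global
    frequency (lexicographic tie-break).  The original transactions are
    retained so supporting identifiers can be recovered by a final scan.
    """

    root: FPNode
    header: dict[Hashable, FPNode]
    item_order: dict[Hashable, int]
    min_support: int
    transactions: list[tuple[Hashable, Itemset]] = field(default_factory=list)

    def item_nodes(self, item: Hashable) -> Iterable[FPNode]:
        node = self.header.get(item)
        while node is not None:
            yield node
            node = node.link

    def dump(self) -> str:
        """Indented text rendering of the tree, for debugging."""
        lines: list[str] = []

        def walk(node: FPNode, depth: int) -> None:
            if node.item is not None:
                lines.append("  " * depth + f"{node.item} ({node.count})")
            for key in sorted(node.children, key=lambda k: self.item_order[k]):
                walk(node.children[key], depth + (node.item is not None))

        walk(self.root, 0)
        return "\n".join(lines) if lines else "(root only)"


@dataclass(frozen=True)
class FrequentItemSet:
    """A frequent itemset with its support and the ids that carry it."""

    items: Itemset
    support: int
    supporting_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("itemset must be non-empty")
        if self.supporting_ids and len(self.supporting_ids) != self.support:
            raise ValueError(
                f"support {self.support} != |supporting_ids| "
                f"{len(self.supporting_ids)}"
            )


def _canonical_key(items: Itemset):
    return (len(items), tuple(sorted(items)))


def build_fp_tree(
    transactions: Sequence[Iterable[Hashable]],
    min_support: int,
    ids: Sequence[Hashable] | None = None,
) -> FPTree:
    """Build the FP-tree over ``transactions`` at the given minimum support.

    ``ids`` optionally names each transaction (defaults to its index);
    the names surface later as ``supporting_ids``.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    tx = [frozenset(t) for t in transactions]
    if ids is None:
        ids = list(range(len(tx)))
    if len(ids) != len(tx):
        raise ValueError("ids and transactions length mismatch")

    freq = Counter(item for t in tx for item in t)
    kept = {item for item, c in freq.items() if c >= min_support}
    # descending frequency, lexicographic tie-break
    ordered = sorted(kept, key=lambda it: (-freq[it], it))
    order = {item: rank for rank, item in enumerate(ordered)}

    root = FPNode(None, None)
    header: dict[Hashable, FPNode] = {}
    tails: dict[Hashable, FPNode] = {}
    for t in tx:
        node = root
        for item in sorted((i for i in t if i in kept), key=order.__getitem__):
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                if item in tails:
                    tails[item].link = child
                else:
                    header[item] = child
                tails[item] = child
            child.count += 1
            node = child

    # keep header in global frequency order
    header = {item: header[item] for item in ordered if item in header}
    return FPTree(
        root=root,
        header=header,
        item_order=order,
        min_support=min_support,
        transactions=list(zip(ids, tx)),
    )


def _mine_tree(
    tree: FPTree, suffix: tuple, min_support: int, out: dict
) -> None:
    # least-frequent-first over the header table
    for item in reversed(list(tree.header)):
        support = sum(node.count for node in tree.item_nodes(item))
        if support < min_support:
            continue
        itemset = frozenset(suffix) | {item}
        out[itemset] = support
        # conditional pattern base: prefix paths weighted by node count
        base: list[tuple[list, int]] = []
        for node in tree.item_nodes(item):
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                base.append((path, node.count))
        if base:
            cond = _build_conditional(base, min_support)
            _mine_tree(cond, tuple(itemset), min_support, out)


def _build_conditional(
    base: list[tuple[list, int]], min_support: int
) -> FPTree:
    freq: Counter = Counter()
    for path, count in base:
        for item in path:
            freq[item] += count
    kept = {item for item, c in freq.items() if c >= min_support}
    ordered = sorted(kept, key=lambda it: (-freq[it], it))
    order = {item: rank for rank, item in enumerate(ordered)}

    root = FPNode(None, None)
    header: dict[Hashable, FPNode] = {}
    tails: dict[Hashable, FPNode] = {}
    for path, count in base:
        node = root
        for item in sorted((i for i in path if i in kept), key=order.__getitem__):
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                if item in tails:
                    tails[item].link = child
                else:
                    header[item] = child
                tails[item] = child
            child.count += count
            node = child
    header = {item: header[item] for item in ordered if item in header}
    return FPTree(root=root, header=header, item_order=order, min_support=min_support)


def mine(tree: FPTree, min_support: int) -> list[FrequentItemSet]:
    """All itemsets with support >= ``min_support``, exactly.

    Supporting transaction ids are recovered by one final scan over the
    transactions retained on the tree; the scan count cross-checks the
    mined support.  Output is canonically sorted (size, then lexicographic),
    hence invariant to transaction input order.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    found: dict[Itemset, int] = {}
    _mine_tree(tree, (), min_support, found)

    results = []
    for itemset, support in found.items():
        ids = frozenset(
            tid for tid, t in tree.transactions if itemset <= t
        )
        if len(ids) != support:  # pragma: no cover - internal consistency
            raise AssertionError(
                f"mined support {support} for {sorted(itemset)} disagrees "
                f"with scan count {len(ids)}"
            )
        results.append(
            FrequentItemSet(items=itemset, support=support, supporting_ids=ids)
        )
    results.sort(key=lambda f: _canonical_key(f.items))
    return results


def fpgrowth(
    transactions: Sequence[Iterable[Hashable]],
    min_support: int,
    ids: Sequence[Hashable] | None = None,
) -> list[FrequentItemSet]:
    """Convenience wrapper: build the tree and mine it."""
    return mine(build_fp_tree(transactions, min_support, ids=ids), min_support)


def brute_force_frequent(
    transactions: Sequence[Iterable[Hashable]],
    min_support: int,
    ids: Sequence[Hashable] | None = None,
) -> list[FrequentItemSet]:
    """Test oracle: enumerate every non-empty subset of the alphabet.

    Guarded to alphabets of at most 20 items.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    tx = [frozenset(t) for t in transactions]
    if ids is None:
        ids = list(range(len(tx)))
    alphabet = sorted({item for t in tx for item in t})
    if len(alphabet) > _BRUTE_FORCE_MAX_ITEMS:
        raise ValueError(
            f"alphabet size {len(alphabet)} exceeds brute-force guard "
            f"({_BRUTE_FORCE_MAX_ITEMS})"
        )
    results = []
    for size in range(1, len(alphabet) + 1):
        for combo in combinations(alphabet, size):
            itemset = frozenset(combo)
            supp_ids = frozenset(
                tid for tid, t in zip(ids, tx) if itemset <= t
            )
            if len(supp_ids) >= min_support:
                results.append(
                    FrequentItemSet(
                        items=itemset,
                        support=len(supp_ids),
                        supporting_ids=supp_ids,
                    )
                )
    results.sort(key=lambda f: _canonical_key(f.items))
    return results


def minimum_support_from_fraction(n_genes: int, fraction: float) -> int:
    """Minimum support count from a fraction of studied genes.

    ``ceil(fraction * n_genes)``, never below 1.  The conventional setting
    is 10% of all studied genes.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return max(1, math.ceil(fraction * n_genes))
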