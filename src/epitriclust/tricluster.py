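"""Phase 3: intersect biclusters across marks into maximal triclusters.

Starting from all valid two-mark intersections, candidates grow breadth
first, one mark at a time, re-intersecting group and gene sets; a
candidate survives only while it keeps >= 2 groups and support at or
above the minimum.  Because intersection only shrinks sets, every prefix
of a surviving candidate also survives, so breadth-first growth reaches
every reachable mark subset regardless of processing order.  The final
list is pruned to maximal triclusters (dominated in marks, groups and
genes simultaneously by another -> dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .bicluster import Bicluster
from .coherence import Item, make_item, pearson
from .preprocess import MarkTensor

#: Candidate cap per breadth-first expansion; overflow raises rather than
#: silently truncating.
DEFAULT_MAX_CANDIDATES = 100_000


@dataclass(frozen=True)
class Tricluster:
    """(mark set x group set x gene set) with support = |genes|."""

    marks: frozenset[str]
    groups: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.marks) < 2:
            raise ValueError("tricluster needs at least 2 marks")
        if len(self.groups) < 2:
            raise ValueError("tricluster needs at least 2 groups")
        if not self.genes:
            raise ValueError("tricluster needs a non-empty gene set")

    @property
    def support(self) -> int:
        return len(self.genes)


class CandidateOverflowError(RuntimeError):
    """Raised when breadth-first growth exceeds the candidate cap."""


def intersect_pair(b1: Bicluster, b2: Bicluster) -> Tricluster | None:
    """Two-mark candidate from two biclusters, or None when degenerate.

    Rejects (returns None) when the group intersection has fewer than two
    groups or the gene intersection is empty.
    """
    if b1.mark == b2.mark:
        raise ValueError(f"both biclusters belong to mark {b1.mark!r}")
    groups = b1.groups & b2.groups
    genes = b1.genes & b2.genes
    if len(groups) < 2 or not genes:
        return None
    return Tricluster(
        marks=frozenset({b1.mark, b2.mark}), groups=groups, genes=genes
    )


def mine_triclusters(
    biclusters_by_mark: dict[str, list[Bicluster]],
    min_support: int,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> list[Tricluster]:
    """All maximal triclusters with support >= ``min_support``."""
    marks = sorted(biclusters_by_mark)
    if len(marks) < 2:
        raise ValueError(f"need biclusters for >= 2 marks, got {len(marks)}")
    for mark, bics in biclusters_by_mark.items():
        for b in bics:
            if b.mark != mark:
                raise ValueError(
                    f"bicluster labelled {b.mark!r} listed under {mark!r}"
                )

    Signature = tuple  # (marks, groups, genes)
    found: dict[Signature, Tricluster] = {}

    def admit(t: Tricluster) -> Signature | None:
        if t.support < min_support:
            return None
        key = (t.marks, t.groups, t.genes)
        if key in found:
            return None
        if len(found) >= max_candidates:
            raise CandidateOverflowError(
                f"more than {max_candidates} tricluster candidates; raise "
                "max_candidates or tighten theta/min_support"
            )
        found[key] = t
        return key

    frontier: list[Tricluster] = []
    for m1, m2 in combinations(marks, 2):
        for b1 in biclusters_by_mark[m1]:
            for b2 in biclusters_by_mark[m2]:
                cand = intersect_pair(b1, b2)
                if cand is not None and admit(cand) is not None:
                    frontier.append(cand)

    while frontier:
        next_frontier: list[Tricluster] = []
        for t in frontier:
            for mark in marks:
                if mark in t.marks:
                    continue
                for b in biclusters_by_mark[mark]:
                    groups = t.groups & b.groups
                    if len(groups) < 2:
                        continue
                    genes = t.genes & b.genes
                    if len(genes) < min_support:
                        continue
                    cand = Tricluster(
                        marks=t.marks | {mark}, groups=groups, genes=genes
                    )
                    if admit(cand) is not None:
                        next_frontier.append(cand)
        frontier = next_frontier

    kept = _drop_dominated(list(found.values()))
    kept.sort(
        key=lambda t: (
            -len(t.marks),
            -len(t.groups),
            -t.support,
            tuple(sorted(t.marks)),
            tuple(sorted(t.groups)),
            tuple(sorted(t.genes)),
        )
    )
    return kept


def _drop_dominated(candidates: list[Tricluster]) -> list[Tricluster]:
    kept = []
    for t in candidates:
        dominated = any(
            o is not t
            and o.marks >= t.marks
            and o.groups >= t.groups
            and o.genes >= t.genes
            for o in candidates
        )
        if not dominated:
            kept.append(t)
    return kept


@dataclass
class VerificationReport:
    """Outcome of recomputing a tricluster's coherence from the tensors."""

    passed: bool
    failures: list[tuple[str, str, Item, float | None]] = field(
        default_factory=list
    )  # (gene, mark, pair, correlation)

    def __str__(self) -> str:
        if self.passed:
            return "PASS"
        lines = [f"FAIL ({len(self.failures)} violations)"]
        for gene, mark, pair, r in self.failures:
            rs = "undefined" if r is None else f"{r:.4f}"
            lines.append(f"  gene={gene} mark={mark} pair={pair}: r={rs}")
        return "\n".join(lines)


def verify_tricluster(
    t: Tricluster,
    tensors: dict[str, MarkTensor],
    theta: float,
) -> VerificationReport:
    """Recompute every within-group pairwise correlation of a tricluster.

    Passes iff for every (gene, mark) in the cluster, every unordered pair
    of its groups correlates at or above theta.  Independent of the mining
    path: reads the tensors directly.
    """
    for mark in t.marks:
        if mark not in tensors:
            raise KeyError(f"no tensor for mark {mark!r}")
    failures: list[tuple[str, str, Item, float | None]] = []
    for mark in sorted(t.marks):
        tensor = tensors[mark]
        for gene in sorted(t.genes):
            if gene not in tensor.genes:
                raise KeyError(f"unknown gene {gene!r} in tensor {mark!r}")
            gi = tensor.gene_index(gene)
            for a, b in combinations(sorted(t.groups), 2):
                if a not in tensor.groups or b not in tensor.groups:
                    missing = a if a not in tensor.groups else b
                    raise KeyError(f"unknown group {missing!r} in tensor {mark!r}")
                r = pearson(
                    tensor.values[tensor.group_index(a), gi],
                    tensor.values[tensor.group_index(b), gi],
                )
                if r is None or r < theta:
                    failures.append((gene, mark, make_item(a, b), r))
    return VerificationReport(passed=not failures, failures=failures)
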