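"""Cross-mark intersection, maximal triclusters, and recomputation guard."""

import numpy as np
import pytest

import epitriclust as et


def bic(mark, groups, genes):
    return et.Bicluster(mark=mark, groups=frozenset(groups),
                        genes=frozenset(genes))


class TestIntersectPair:
    def test_set_intersections(self):
        b1 = bic("m1", "ABC", [f"g{i}" for i in range(1, 11)])
        b2 = bic("m2", "ABD", [f"g{i}" for i in range(5, 15)])
        t = et.intersect_pair(b1, b2)
        assert t.marks == frozenset({"m1", "m2"})
        assert t.groups == frozenset("AB")
        assert t.genes == frozenset(f"g{i}" for i in range(5, 11))
        assert t.support == 6

    def test_disjoint_gene_sets_rejected(self):
        assert et.intersect_pair(
            bic("m1", "AB", ["g1"]), bic("m2", "AB", ["g2"])
        ) is None

    def test_single_shared_group_rejected(self):
        assert et.intersect_pair(
            bic("m1", "AB", ["g1"]), bic("m2", "AC", ["g1"])
        ) is None

    def test_same_mark_is_an_error(self):
        with pytest.raises(ValueError, match="same|mark"):
            et.intersect_pair(bic("m1", "AB", ["g1"]), bic("m1", "AB", ["g1"]))


class TestMineTriclusters:
    def test_identical_biclusters_across_two_marks(self):
        by_mark = {
            "m1": [bic("m1", "ABC", ["g1", "g2", "g3"])],
            "m2": [bic("m2", "ABC", ["g1", "g2", "g3"])],
        }
        (t,) = et.mine_triclusters(by_mark, 2)
        assert t.marks == frozenset({"m1", "m2"})
        assert t.groups == frozenset("ABC")
        assert t.genes == frozenset({"g1", "g2", "g3"})

    def test_min_support_above_every_intersection_empty(self):
        by_mark = {
            "m1": [bic("m1", "AB", ["g1", "g2"])],
            "m2": [bic("m2", "AB", ["g1", "g2"])],
        }
        assert et.mine_triclusters(by_mark, 3) == []

    def test_fewer_than_two_marks_is_an_error(self):
        with pytest.raises(ValueError, match="2 marks"):
            et.mine_triclusters({"m1": [bic("m1", "AB", ["g1"])]}, 1)

    def test_three_mark_growth_beats_its_two_mark_prefixes(self):
        genes = [f"g{i}" for i in range(10)]
        by_mark = {m: [bic(m, "ABC", genes)] for m in ("m1", "m2", "m3")}
        (t,) = et.mine_triclusters(by_mark, 5)
        assert t.marks == frozenset({"m1", "m2", "m3"})  # prefixes dominated

    def test_planted_blocks_recovered_exactly_zero_noise(self, zero_noise_world):
        truth = zero_noise_world["truth"]
        tris = zero_noise_world["triclusters"]
        report = et.score_recovery(tris, truth)
        assert report.all_exact
        # and the recovered blocks sit at the top of the canonical order
        top = {(t.marks, t.groups, t.genes) for t in tris[: len(truth)]}
        assert top == {(b.marks, b.groups, b.genes) for b in truth}

    def test_support_anti_monotone_when_adding_marks(self, zero_noise_world):
        """Every k-mark tricluster has support <= any (k-1)-mark
        tricluster over a mark subset with superset groups."""
        tris = zero_noise_world["triclusters"]
        ms = zero_noise_world["min_support"]
        by_mark = zero_noise_world["biclusters"]
        for t in tris:
            for drop in t.marks:
                sub_marks = t.marks - {drop}
                if len(sub_marks) < 2:
                    continue
                sub = et.mine_triclusters(
                    {m: by_mark[m] for m in sub_marks}, ms
                )
                parents = [
                    s for s in sub
                    if s.groups >= t.groups and s.genes >= t.genes
                ]
                assert parents
                assert all(s.support >= t.support for s in parents)

    def test_order_invariance_of_mark_processing(self, zero_noise_world):
        by_mark = zero_noise_world["biclusters"]
        ms = zero_noise_world["min_support"]
        base = et.mine_triclusters(by_mark, ms)
        reordered = dict(reversed(list(by_mark.items())))
        assert et.mine_triclusters(reordered, ms) == base

    def test_maximality_no_dominated_tricluster_reported(self, zero_noise_world):
        tris = zero_noise_world["triclusters"]
        for t in tris:
            assert not any(
                o is not t
                and o.marks >= t.marks
                and o.groups >= t.groups
                and o.genes >= t.genes
                for o in tris
            )

    def test_candidate_cap_overflow_raises(self):
        from epitriclust.tricluster import CandidateOverflowError

        genes = [f"g{i}" for i in range(4)]
        by_mark = {
            m: [bic(m, "ABCD", genes), bic(m, "ABC", genes[:3]),
                bic(m, "ABD", genes[:3])]
            for m in ("m1", "m2", "m3")
        }
        with pytest.raises(CandidateOverflowError):
            et.mine_triclusters(by_mark, 1, max_candidates=2)


class TestVerifyTricluster:
    def test_all_mined_triclusters_pass_on_planted_data(self, zero_noise_world):
        for t in zero_noise_world["triclusters"]:
            report = et.verify_tricluster(
                t, zero_noise_world["tensors"], theta=0.65
            )
            assert report.passed and not report.failures

    def test_corrupted_gene_named_in_failure_report(self, zero_noise_world):
        tensors = {
            m: et.MarkTensor(
                t.mark, list(t.groups), list(t.genes), t.n_bins,
                t.values.copy(),
            )
            for m, t in zero_noise_world["tensors"].items()
        }
        t0 = zero_noise_world["triclusters"][0]
        gene = sorted(t0.genes)[0]
        mark = sorted(t0.marks)[0]
        group = sorted(t0.groups)[0]
        tensor = tensors[mark]
        gi = tensor.gene_index(gene)
        tensor.values[tensor.group_index(group), gi] = np.arange(
            tensor.n_bins, 0, -1.0
        ) * tensor.values[tensor.group_index(group), gi].max()
        report = et.verify_tricluster(t0, tensors, theta=0.65)
        assert not report.passed
        assert any(
            g == gene and m == mark and group in pair
            for g, m, pair, _ in report.failures
        )
        assert gene in str(report)

    def test_unknown_group_label_is_an_error(self, zero_noise_world):
        t0 = zero_noise_world["triclusters"][0]
        bad = et.Tricluster(
            marks=t0.marks,
            groups=frozenset({"nope", *list(t0.groups)[:1]}),
            genes=t0.genes,
        )
        with pytest.raises(KeyError, match="nope"):
            et.verify_tricluster(bad, zero_noise_world["tensors"], 0.65)

    def test_missing_tensor_for_mark_is_an_error(self, zero_noise_world):
        t0 = zero_noise_world["triclusters"][0]
        tensors = dict(zero_noise_world["tensors"])
        tensors.pop(sorted(t0.marks)[0])
        with pytest.raises(KeyError, match="no tensor"):
            et.verify_tricluster(t0, tensors, 0.65)
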