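"""Identification criteria against hand-built cases and brute-force rules."""

import numpy as np
import pytest

from barcodeval.distances import DistanceMatrix
from barcodeval.identification import (
    FALLBACK_THRESHOLD,
    IdOutcome,
    best_close_match,
    kde_on_grid,
    local_minima_threshold,
    near_neighbour,
    silverman_bandwidth,
    summarize_outcomes,
    thresh_id,
)

from conftest import make_specimens


def matrix_from(labels, d):
    return DistanceMatrix(labels=tuple(labels), d=np.array(d, dtype=float))


def simple_case():
    """Two species, two specimens each, clean separation."""
    labels = "a1 a2 b1 b2".split()
    d = np.array(
        [
            [0, 0.001, 0.05, 0.05],
            [0.001, 0, 0.05, 0.05],
            [0.05, 0.05, 0, 0.002],
            [0.05, 0.05, 0.002, 0],
        ]
    )
    return matrix_from(labels, d), make_specimens(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    )


class TestNearNeighbour:
    def test_clean_case_all_true(self):
        m, sp = simple_case()
        _, summary = near_neighbour(m, sp)
        assert summary.percentages == {"true": 100, "false": 0}

    def test_singleton_forced_false(self):
        m = matrix_from("x b1 b2".split(), [[0, 0.02, 0.03], [0.02, 0, 0.01], [0.03, 0.01, 0]])
        out, _ = near_neighbour(m, make_specimens({"x": "X", "b1": "B", "b2": "B"}))
        assert next(o for o in out if o.specimen_id == "x").category == "false"

    def test_tie_scored_optimistically(self):
        m = matrix_from(
            "q c h".split(),
            [[0, 0.01, 0.01], [0.01, 0, 0.02], [0.01, 0.02, 0]],
        )
        out, _ = near_neighbour(m, make_specimens({"q": "A", "c": "A", "h": "B"}))
        assert next(o for o in out if o.specimen_id == "q").category == "true"


class TestBestCloseMatch:
    def test_rule_table(self):
        labels = "q c h f".split()
        d = np.array(
            [
                [0, 0.004, 0.02, 0.5],
                [0.004, 0, 0.02, 0.5],
                [0.02, 0.02, 0, 0.5],
                [0.5, 0.5, 0.5, 0],
            ]
        )
        m = matrix_from(labels, d)
        sp = make_specimens({"q": "A", "c": "A", "h": "B", "f": "C"})
        out, _ = best_close_match(m, sp, 0.005)
        by_id = {o.specimen_id: o.category for o in out}
        assert by_id["q"] == "correct"  # conspecific at 0.004 <= 0.005
        assert by_id["h"] == "no_id"  # nothing within 0.005
        assert by_id["f"] == "no_id"

    def test_tie_at_minimum_is_ambiguous(self):
        m = matrix_from(
            "q c h".split(),
            [[0, 0.004, 0.004], [0.004, 0, 0.02], [0.004, 0.02, 0]],
        )
        out, _ = best_close_match(m, make_specimens({"q": "A", "c": "A", "h": "B"}), 0.01)
        assert next(o for o in out if o.specimen_id == "q").category == "ambiguous"

    def test_threshold_inclusive(self):
        m = matrix_from(
            "q c h".split(),
            [[0, 0.01, 0.5], [0.01, 0, 0.5], [0.5, 0.5, 0]],
        )
        out, _ = best_close_match(m, make_specimens({"q": "A", "c": "A", "h": "B"}), 0.01)
        assert next(o for o in out if o.specimen_id == "q").category == "correct"


class TestThreshId:
    def test_contrast_with_best_close_match(self):
        """A heterospecific inside the threshold but behind the nearest
        conspecific poisons the BOLD candidate set, not the best match."""
        m = matrix_from(
            "q c h".split(),
            [[0, 0.004, 0.008], [0.004, 0, 0.02], [0.008, 0.02, 0]],
        )
        sp = make_specimens({"q": "A", "c": "A", "h": "B"})
        bold, _ = thresh_id(m, sp, 0.01)
        bcm, _ = best_close_match(m, sp, 0.01)
        assert next(o for o in bold if o.specimen_id == "q").category == "ambiguous"
        assert next(o for o in bcm if o.specimen_id == "q").category == "correct"

    def test_pure_candidate_set_correct(self):
        m, sp = simple_case()
        out, summary = thresh_id(m, sp, 0.01)
        assert summary.percentages["correct"] == 100

    def test_empty_candidate_set_no_id(self):
        m, sp = simple_case()
        out, _ = thresh_id(m, sp, 0.0005)
        cats = {o.specimen_id: o.category for o in out}
        assert cats["b1"] == "no_id"  # nearest (0.002) outside 0.0005


class TestBruteForceAgreement:
    """Exhaustive small-matrix enumeration against independent rule tables."""

    @staticmethod
    def oracle_bcm(d, species, q, threshold):
        others = [j for j in range(len(species)) if j != q]
        within = [j for j in others if d[q][j] <= threshold]
        if not within:
            return "no_id"
        dmin = min(d[q][j] for j in within)
        best = [j for j in within if d[q][j] == dmin]
        kinds = {species[j] == species[q] for j in best}
        if kinds == {True}:
            return "correct"
        if kinds == {False}:
            return "incorrect"
        return "ambiguous"

    @staticmethod
    def oracle_thresh(d, species, q, threshold):
        others = [j for j in range(len(species)) if j != q]
        within = [j for j in others if d[q][j] <= threshold]
        if not within:
            return "no_id"
        kinds = {species[j] == species[q] for j in within}
        if kinds == {True}:
            return "correct"
        if kinds == {False}:
            return "incorrect"
        return "ambiguous"

    @staticmethod
    def partitions(n):
        """All species assignments of n specimens (set partitions)."""
        if n == 1:
            yield [0]
            return
        for rest in TestBruteForceAgreement.partitions(n - 1):
            k = max(rest) + 1
            for block in range(k + 1):
                yield rest + [block]

    def test_exhaustive_four_specimens(self):
        self._run_exhaustive(n=4)

    def test_exhaustive_three_specimens(self):
        self._run_exhaustive(n=3)

    def _run_exhaustive(self, n, grid=(0.002, 0.01, 0.05), threshold=0.01):
        import itertools

        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for assignment in self.partitions(n):
            species_names = [f"sp{a}" for a in assignment]
            if len(set(species_names)) < 2:
                continue
            specimens = make_specimens(
                {f"s{i}": species_names[i] for i in range(n)}
            )
            labels = [f"s{i}" for i in range(n)]
            for values in itertools.product(grid, repeat=len(pairs)):
                d = np.zeros((n, n))
                for (i, j), v in zip(pairs, values):
                    d[i, j] = d[j, i] = v
                m = DistanceMatrix(labels=tuple(labels), d=d)
                bcm_out, _ = best_close_match(m, specimens, threshold)
                bold_out, _ = thresh_id(m, specimens, threshold)
                for q in range(n):
                    want_bcm = self.oracle_bcm(d, species_names, q, threshold)
                    want_bold = self.oracle_thresh(d, species_names, q, threshold)
                    assert bcm_out[q].category == want_bcm
                    assert bold_out[q].category == want_bold
                    # implication: a pure BOLD set forces a correct best match
                    if want_bold == "correct":
                        assert want_bcm == "correct"


class TestThresholdOptimiser:
    def test_bimodal_mixture_threshold_in_gap(self):
        rng = np.random.default_rng(31)
        intra = np.abs(rng.normal(0.002, 0.001, 150))
        inter = rng.normal(0.05, 0.01, 150)
        est = local_minima_threshold(np.concatenate([intra, inter]))
        assert not est.fallback
        assert 0.005 < est.threshold < 0.04

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(37)
        x = np.concatenate(
            [np.abs(rng.normal(0.002, 0.001, 100)), rng.normal(0.05, 0.01, 100)]
        )
        est = local_minima_threshold(x)
        bw = silverman_bandwidth(x)
        dense = np.linspace(x.min(), x.max(), 8192)
        dd = kde_on_grid(x, dense, bw)
        mins = [
            dense[i]
            for i in range(1, len(dense) - 1)
            if dd[i] < dd[i - 1] and dd[i] < dd[i + 1]
        ]
        assert mins
        grid_step = (x.max() - x.min()) / 511
        assert abs(est.threshold - mins[0]) <= grid_step

    def test_trimodal_has_multiple_minima_first_returned(self):
        rng = np.random.default_rng(41)
        x = np.concatenate(
            [
                rng.normal(0.002, 0.0005, 120),
                rng.normal(0.03, 0.002, 120),
                rng.normal(0.09, 0.004, 120),
            ]
        )
        est = local_minima_threshold(x)
        assert len(est.all_local_minima) >= 2
        assert est.threshold == est.all_local_minima[0]

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(43)
        est = local_minima_threshold(rng.normal(0.05, 0.002, 300))
        assert est.fallback
        assert est.threshold == FALLBACK_THRESHOLD

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError, match="10"):
            local_minima_threshold([0.01] * 9)


class TestSummaries:
    def test_percentages_printed_example(self):
        outcomes = (
            [_mk("correct")] * 76 + [_mk("incorrect")] * 8 + [_mk("no_id")] * 3
        )
        s = summarize_outcomes(outcomes)
        assert s.n_queries == 87
        # 76/87 = 87.4%, 8/87 = 9.2%, 3/87 = 3.4%; the leftover percent
        # point goes to the largest remainder so the row sums to 100
        assert s.percentages == {
            "ambiguous": 0,
            "correct": 87,
            "incorrect": 9,
            "no_id": 4,
        }

    def test_all_correct(self):
        s = summarize_outcomes([_mk("correct")] * 5)
        assert s.percentages["correct"] == 100

    def test_single_query(self):
        s = summarize_outcomes([_mk("ambiguous")])
        assert s.percentages["ambiguous"] == 100

    def test_percentages_sum_near_100(self):
        rng = np.random.default_rng(47)
        cats = ["ambiguous", "correct", "incorrect", "no_id"]
        for _ in range(200):
            n = int(rng.integers(1, 200))
            outcomes = [_mk(cats[k]) for k in rng.integers(0, 4, n)]
            total = sum(summarize_outcomes(outcomes).percentages.values())
            assert total == 100

    def test_mixed_criteria_rejected(self):
        nn = IdOutcome("q", "A", "near_neighbour", "true")
        with pytest.raises(ValueError, match="mixed"):
            summarize_outcomes([_mk("correct"), nn])

    def test_illegal_category_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            IdOutcome("q", "A", "near_neighbour", "correct")


def _mk(category):
    return IdOutcome("q", "A", "best_close_match", category)


class TestMonotonicity:
    def test_raising_threshold_never_increases_no_id(self):
        rng = np.random.default_rng(53)
        n = 12
        d = rng.random((n, n)) * 0.05
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        sp = make_specimens({lab: f"sp{i % 4}" for i, lab in enumerate(labels)})
        m = DistanceMatrix(labels=tuple(labels), d=d)
        prev_bcm = prev_bold = None
        for thr in (0.005, 0.01, 0.02, 0.04):
            _, s_bcm = best_close_match(m, sp, thr)
            _, s_bold = thresh_id(m, sp, thr)
            if prev_bcm is not None:
                assert s_bcm.counts["no_id"] <= prev_bcm
                assert s_bold.counts["no_id"] <= prev_bold
            prev_bcm = s_bcm.counts["no_id"]
            prev_bold = s_bold.counts["no_id"]
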