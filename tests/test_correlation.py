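"""Target-correlation mining: filters, pairing, Spearman, CI, selection."""

import itertools

import numpy as np
import pytest
from scipy import stats

import chemcascade as cc
from chemcascade.correlation import TargetCorrelationResult, bootstrap_rho_interval, correlate
from chemcascade.errors import (
    DuplicateKeyError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

from conftest import make_cell_record, make_target_record


def brute_spearman(x, y):
    """Average ranks computed explicitly, then Pearson on the ranks."""

    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    return float(np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1])


class TestTargetFilter:
    def test_six_clauses(self):
        good = make_target_record()
        bads = [
            make_target_record(standard_type="GI50"),
            make_target_record(relation="<"),
            make_target_record(units="uM"),
            make_target_record(target_type="Protein complex"),
            make_target_record(organism="Rattus norvegicus"),
            make_target_record(assay="F"),
        ]
        out = cc.filter_target_bioactivities([good] + bads)
        assert out == [good]

    def test_dedup_applied_after_clauses(self):
        a = make_target_record("c1", "T1", value=100)
        b = make_target_record("c1", "T1", value=20)
        out = cc.filter_target_bioactivities([a, b])
        assert len(out) == 1 and out[0].standard_value == 20


class TestMinAnnotationFilter:
    def test_boundary_at_minimum(self):
        recs = [make_target_record(f"c{i}", "T10", value=i + 1) for i in range(10)]
        recs += [make_target_record(f"c{i}", "T9", value=i + 1) for i in range(9)]
        assert cc.min_annotation_filter(recs, 10) == ["T10"]

    def test_empty_input(self):
        assert cc.min_annotation_filter([], 10) == []

    def test_counts_distinct_compounds_not_rows(self):
        recs = [make_target_record("c1", "T1", value=v) for v in range(1, 12)]
        assert cc.min_annotation_filter(recs, 10) == []


class TestBuildPairs:
    def test_inner_join_semantics(self):
        targets = [make_target_record(f"c{i}", "T1", value=10 * (i + 1)) for i in range(12)]
        cells = [make_cell_record(f"c{i}", "PC-3", value=5 * (i + 1)) for i in range(8)]
        vec = cc.build_pairs(targets, cells, "PC-3")
        assert vec.n == 8
        assert vec.target_id == "T1" and vec.cell_line == "PC-3"

    def test_no_shared_compounds_gives_empty_vector(self):
        vec = cc.build_pairs(
            [make_target_record("c1")], [make_cell_record("c2")], "PC-3"
        )
        assert vec.n == 0

    def test_duplicates_rejected(self):
        cells = [make_cell_record("c1", value=10), make_cell_record("c1", value=20)]
        with pytest.raises(DuplicateKeyError):
            cc.build_pairs([make_target_record("c1")], cells, "PC-3")


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = cc.spearman([100, 200, 300, 400], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        rho, _ = cc.spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_classical_rank_difference_formula(self):
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/(5*24)
        rho, _ = cc.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-14)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 1e4, 25)
        y = rng.uniform(10, 1e4, 25)
        r1, p1 = cc.spearman(x, y)
        r2, p2 = cc.spearman(-np.log10(x), y)
        assert r1 == pytest.approx(-r2, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            cc.spearman([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            cc.spearman([1, 1, 1], [1, 2, 3])

    def test_exhaustive_small_domain_oracle(self):
        """Tie-aware agreement with the brute-force route on {1,2,3} vectors."""
        levels = (1, 2, 3)
        checked = 0
        # all (x, y) pairs at n=3 and n=4
        for n in (3, 4):
            vecs = [v for v in itertools.product(levels, repeat=n) if len(set(v)) > 1]
            for x in vecs:
                for y in vecs:
                    rho, _ = cc.spearman(x, y)
                    assert abs(rho - brute_spearman(x, y)) < 1e-12
                    checked += 1
        # all y at n=5..8 against a fixed untied x
        for n in range(5, 9):
            x = tuple(range(1, n + 1))
            for y in itertools.product(levels, repeat=n):
                if len(set(y)) == 1:
                    continue
                rho, _ = cc.spearman(x, y)
                assert abs(rho - brute_spearman(x, y)) < 1e-12
                checked += 1
        assert checked > 10000

    def test_p_value_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = cc.spearman(x, y)
        t = rho * np.sqrt((20 - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)


class TestConfidenceInterval:
    def test_closed_form_oracle(self):
        rho, n, level = 0.6, 30, 0.95
        lo, hi = cc.rho_confidence_interval(rho, n, level)
        se = np.sqrt((1 + rho**2 / 2) / (n - 3))
        z = np.arctanh(rho)
        zc = stats.norm.ppf(0.975)
        assert lo == pytest.approx(np.tanh(z - zc * se), abs=1e-10)
        assert hi == pytest.approx(np.tanh(z + zc * se), abs=1e-10)

    def test_symmetric_about_zero(self):
        lo, hi = cc.rho_confidence_interval(0.0, 200)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_nesting(self):
        lo95, hi95 = cc.rho_confidence_interval(0.5, 40, 0.95)
        lo99, hi99 = cc.rho_confidence_interval(0.5, 40, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_contains_rho(self):
        lo, hi = cc.rho_confidence_interval(0.7, 25)
        assert lo < 0.7 < hi

    def test_too_few_raises(self):
        with pytest.raises(InsufficientDataError):
            cc.rho_confidence_interval(0.5, 3)

    def test_bootstrap_alternative_brackets_strong_signal(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 50)
        y = x + rng.normal(0, 0.2, 50)
        lo, hi = bootstrap_rho_interval(x, y, seed=5)
        rho, _ = cc.spearman(x, y)
        assert lo < rho < hi
        assert (lo, hi) == bootstrap_rho_interval(x, y, seed=5)  # seeded


class TestSelectTargets:
    def make(self, rho, p, ci_low):
        return TargetCorrelationResult("T", "PC-3", 30, rho, p, ci_low, 0.99, False)

    def test_all_three_criteria(self):
        assert cc.select_targets([self.make(0.55, 1e-4, 0.42)]) != []

    def test_ci_clause_rejects(self):
        assert cc.select_targets([self.make(0.55, 1e-4, 0.31)]) == []
        assert cc.select_targets([self.make(0.55, 1e-4, 0.31)], require_ci=False) != []

    def test_rho_floor_rejects(self):
        assert cc.select_targets([self.make(0.39, 1e-4, 0.35)]) == []

    def test_degenerate_vector_reported_not_raised(self):
        vec = cc.PairedPotencyVector("T", "PC-3", (("c1", 1.0, 2.0), ("c2", 1.0, 3.0), ("c3", 1.0, 4.0)))
        res = correlate(vec)
        assert not res.selected and res.diagnostic == "zero variance"


class TestRestrictedPairing:
    def test_restriction_keeps_only_potent_cell_pairs(self):
        targets = [make_target_record(f"c{i}", "T1", value=10.0 * (i + 1)) for i in range(6)]
        cells = [
            make_cell_record(f"c{i}", "PC-3", value=v)
            for i, v in enumerate([100, 900, 1000, 1500, 5000, 800])
        ]
        full = cc.build_pairs(targets, cells, "PC-3")
        restricted = cc.build_pairs(targets, cells, "PC-3", restrict_to_highly_active=True)
        assert full.n == 6 and restricted.n == 4
        assert all(p[2] <= 1000 for p in restricted.pairs)
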