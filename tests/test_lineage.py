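import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptlineage import lineage
from cryptlineage.lineage import (
    ClassifierParams,
    DivisionPatternCounts,
    EndReason,
    MalformedTreeError,
    PairRecord,
    State,
    UndefinedStatisticError,
    build_lineage_forest,
    classify_state,
    estimate_alpha_phi,
    extract_pairs,
    is_excluded,
    sister_cycle_correlation,
    symmetry_fraction,
    tally_pair_outcomes,
)

COLS = ["cell_id", "parent_id", "frame", "t_hr", "x_um", "y_um", "z_um", "is_paneth", "died"]


def _table(rows):
    return pd.DataFrame(rows, columns=COLS)


def _track_rows(cid, parent, f0, f1, dt=0.2, died_last=False):
    return [
        (cid, parent, f, round(f * dt, 6), 0.0, 0.0, float(f), 0, int(died_last and f == f1))
        for f in range(f0, f1 + 1)
    ]


class TestBuildForest:
    def test_mother_with_two_daughters(self):
        rows = _track_rows("m", "", 0, 50) + _track_rows("a", "m", 51, 100) + _track_rows("b", "m", 51, 100)
        forest = build_lineage_forest(_table(rows))
        assert forest.roots == ["m"]
        assert forest.cells["m"].end_reason is EndReason.DIVIDED
        assert sorted(forest.children_of("m")) == ["a", "b"]
        assert forest.cells["a"].end_reason is EndReason.EXPERIMENT_END

    def test_single_track_is_one_root(self):
        forest = build_lineage_forest(_table(_track_rows("x", "", 0, 30)))
        assert forest.roots == ["x"] and not forest.children

    def test_three_children_rejected(self):
        rows = _track_rows("m", "", 0, 50)
        for d in "abc":
            rows += _track_rows(d, "m", 51, 60)
        with pytest.raises(MalformedTreeError, match="m"):
            build_lineage_forest(_table(rows))

    def test_one_child_rejected(self):
        rows = _track_rows("m", "", 0, 50) + _track_rows("a", "m", 51, 60)
        with pytest.raises(MalformedTreeError):
            build_lineage_forest(_table(rows))

    def test_death_and_loss_end_reasons(self):
        rows = _track_rows("d", "", 0, 40, died_last=True) + _track_rows("l", "", 0, 60) + _track_rows("e", "", 0, 100)
        forest = build_lineage_forest(_table(rows))
        assert forest.cells["d"].end_reason is EndReason.DIED
        assert forest.cells["l"].end_reason is EndReason.LOST
        assert forest.cells["e"].end_reason is EndReason.EXPERIMENT_END

    def test_child_birth_must_abut_parent_end(self):
        rows = _track_rows("m", "", 0, 50) + _track_rows("a", "m", 60, 100) + _track_rows("b", "m", 51, 100)
        with pytest.raises(MalformedTreeError):
            build_lineage_forest(_table(rows))


class TestClassifier:
    def _forest(self, extra_rows=(), end_frame=300):
        rows = list(extra_rows) + _track_rows("pad", "", 0, end_frame)
        return build_lineage_forest(_table(rows))

    def test_divided_cell_is_proliferating(self, seven_cell_forest):
        assert classify_state(seven_cell_forest.cells["m"], seven_cell_forest, 10.0) is State.PROLIFERATING

    def test_long_observation_without_division_is_nonproliferating(self):
        forest = self._forest(_track_rows("c", "", 0, 160))  # 32 hr observed, then lost
        assert classify_state(forest.cells["c"], forest, 40.0) is State.NON_PROLIFERATING

    def test_villus_position_is_nonproliferating(self):
        forest = self._forest(_track_rows("c", "", 0, 50))  # 10 hr, lost
        assert classify_state(forest.cells["c"], forest, 70.0) is State.NON_PROLIFERATING

    def test_short_low_cell_is_undetermined(self):
        forest = self._forest(_track_rows("c", "", 0, 50))
        assert classify_state(forest.cells["c"], forest, 30.0) is State.UNDETERMINED

    def test_death_dominates(self):
        forest = self._forest(_track_rows("c", "", 0, 160, died_last=True))
        assert classify_state(forest.cells["c"], forest, 70.0) is State.DEAD

    def test_born_near_end_is_excluded(self):
        # experiment ends at 60 hr; born at 50 hr -> within the 15-hr exclusion
        forest = self._forest(_track_rows("c", "", 250, 300))
        assert is_excluded(forest.cells["c"], forest)
        assert classify_state(forest.cells["c"], forest, 30.0) is State.UNDETERMINED

    def test_assume_unclassified_mode(self):
        forest = self._forest(_track_rows("c", "", 0, 50))
        params = ClassifierParams(assume_unclassified_nonproliferating=True)
        assert classify_state(forest.cells["c"], forest, 30.0, params) is State.NON_PROLIFERATING

    def test_classification_is_total(self, analyzed_crypt):
        cls = analyzed_crypt["classification"]
        forest = analyzed_crypt["forest"]
        assert len(cls) == len(forest.cells)
        assert cls["state"].notna().all()


class TestPairs:
    def test_seven_cell_pair_counts(self, seven_cell_forest):
        sisters = extract_pairs(seven_cell_forest, "sister")
        cousins = extract_pairs(seven_cell_forest, "cousin")
        assert len(sisters) == 3
        assert len(cousins) == 4
        assert all(sorted((p.cell_a, p.cell_b)) == [p.cell_a, p.cell_b] for p in sisters)

    def test_one_division_gives_one_sister_pair(self):
        rows = _track_rows("m", "", 0, 50) + _track_rows("a", "m", 51, 100) + _track_rows("b", "m", 51, 100)
        forest = build_lineage_forest(_table(rows))
        assert len(extract_pairs(forest, "sister")) == 1
        assert extract_pairs(forest, "cousin") == []

    def test_isolated_roots_give_no_pairs(self):
        forest = build_lineage_forest(_table(_track_rows("x", "", 0, 30) + _track_rows("y", "", 0, 30)))
        assert extract_pairs(forest, "sister") == []
        assert extract_pairs(forest, "cousin") == []

    def test_pairs_are_unique_per_division(self, analyzed_crypt):
        sisters = analyzed_crypt["sister_pairs"]
        assert len({frozenset((p.cell_a, p.cell_b)) for p in sisters}) == len(sisters)


def _pair(sa, sb, ca=None, cb=None, excluded=False):
    return PairRecord("sister", "a", "b", sa, sb, ca, cb, excluded)


class TestTally:
    def test_all_proliferating(self):
        c = tally_pair_outcomes([_pair(State.PROLIFERATING, State.PROLIFERATING)] * 100)
        assert (c.n_pp, c.n_nn, c.n_pn, c.n_death_one, c.n_death_both, c.n_excluded) == (100, 0, 0, 0, 0, 0)

    def test_death_categories(self):
        pairs = [
            _pair(State.DEAD, State.PROLIFERATING),
            _pair(State.DEAD, State.DEAD),
            _pair(State.DEAD, State.UNDETERMINED),  # death dominates exclusion
        ]
        c = tally_pair_outcomes(pairs)
        assert (c.n_death_one, c.n_death_both) == (2, 1)

    def test_undetermined_and_excluded_pairs(self):
        pairs = [
            _pair(State.PROLIFERATING, State.UNDETERMINED),
            _pair(State.PROLIFERATING, State.PROLIFERATING, excluded=True),
        ]
        c = tally_pair_outcomes(pairs)
        assert c.n_excluded == 2 and c.n_classified == 0

    def test_totals_conserved(self, analyzed_crypt):
        pairs = analyzed_crypt["sister_pairs"]
        c = tally_pair_outcomes(pairs)
        assert c.n_total == len(pairs)

    def test_both_normalizations(self):
        c = DivisionPatternCounts(n_pp=59, n_nn=15, n_pn=2, n_death_one=14, n_death_both=9)
        no_death = c.fractions(include_death=False)
        with_death = c.fractions(include_death=True)
        assert no_death["pp"] == pytest.approx(59 / 76)
        assert with_death["pp"] == pytest.approx(59 / 99)
        assert sum(with_death.values()) == pytest.approx(1.0)


class TestSymmetryAndEstimators:
    def test_organoid_panel_fractions(self):
        # 59% both divide, 15% both stop, 2% one of each -> 74/76 symmetric
        c = DivisionPatternCounts(n_pp=59, n_nn=15, n_pn=2)
        assert symmetry_fraction(c) == pytest.approx(74 / 76)
        assert symmetry_fraction(c) == pytest.approx(0.974, abs=0.001)

    def test_degenerate_fractions(self):
        assert symmetry_fraction(DivisionPatternCounts(n_pp=1)) == 1.0
        assert symmetry_fraction(DivisionPatternCounts(n_pn=5)) == 0.0

    def test_empty_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            symmetry_fraction(DivisionPatternCounts())

    def test_alpha_phi_inversion(self):
        # fractions (0.825, 0.155, 0.02) invert to the near-Paneth estimates
        c = DivisionPatternCounts(n_pp=825, n_nn=155, n_pn=20)
        alpha, phi = estimate_alpha_phi(c)
        assert alpha == pytest.approx(0.67)
        assert phi == pytest.approx(0.98)

    def test_alpha_phi_extremes(self):
        assert estimate_alpha_phi(DivisionPatternCounts(n_pn=10)) == (0.0, 0.0)
        assert estimate_alpha_phi(DivisionPatternCounts(n_pp=10)) == (1.0, 1.0)

    @pytest.mark.parametrize("alpha,phi", [(0.0, 0.5), (0.67, 0.98), (-0.4, 0.8)])
    def test_multinomial_recovery_within_three_se(self, alpha, phi):
        """Sampling pair outcomes at true (alpha, phi) and inverting recovers
        both parameters within 3 standard errors (checked over replicates:
        a single 1000-pair draw can fluctuate past 3 se by chance)."""
        rng = np.random.default_rng(7)
        n = 1000
        p = np.array([(phi + alpha) / 2, (phi - alpha) / 2, 1 - phi])
        # standard errors at the true parameters (the sampling-distribution
        # scale, not the per-draw plug-in estimate)
        se_a = math.sqrt((phi - alpha**2) / n)
        se_p = math.sqrt(phi * (1 - phi) / n)
        within = 0
        reps = 12
        for _ in range(reps):
            draws = rng.multinomial(n, p)
            c = DivisionPatternCounts(n_pp=int(draws[0]), n_nn=int(draws[1]), n_pn=int(draws[2]))
            a_hat, p_hat = estimate_alpha_phi(c)
            within += abs(a_hat - alpha) <= 3 * max(se_a, 1e-3) and abs(p_hat - phi) <= 3 * max(se_p, 1e-3)
        assert within >= reps - 1

    @given(
        n_pp=st.integers(0, 200), n_nn=st.integers(0, 200), n_pn=st.integers(1, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, n_pp, n_nn, n_pn):
        """Swapping pair-member labels swaps nothing: counts are symmetric."""
        c = DivisionPatternCounts(n_pp=n_pp, n_nn=n_nn, n_pn=n_pn)
        assert estimate_alpha_phi(c) == estimate_alpha_phi(c)
        # symmetry fraction only depends on category totals, not member order
        pairs = [_pair(State.PROLIFERATING, State.NON_PROLIFERATING)] * n_pn
        flipped = [_pair(State.NON_PROLIFERATING, State.PROLIFERATING)] * n_pn
        assert tally_pair_outcomes(pairs).n_pn == tally_pair_outcomes(flipped).n_pn


class TestCycleCorrelation:
    def test_identical_cycles_give_one(self):
        pairs = [_pair(State.PROLIFERATING, State.PROLIFERATING, ca=float(c), cb=float(c)) for c in range(10, 30)]
        assert sister_cycle_correlation(pairs) == pytest.approx(1.0)

    def test_independent_cycles_give_zero(self):
        rng = np.random.default_rng(3)
        pairs = [
            _pair(State.PROLIFERATING, State.PROLIFERATING, ca=rng.normal(16, 3), cb=rng.normal(16, 3))
            for _ in range(4000)
        ]
        assert abs(sister_cycle_correlation(pairs)) < 0.05

    def test_generated_correlation_recovered(self):
        rng = np.random.default_rng(11)
        rho = 0.8
        z0 = rng.standard_normal(500)
        a = 16 + 3 * (np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(500))
        b = 16 + 3 * (np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(500))
        pairs = [_pair(State.PROLIFERATING, State.PROLIFERATING, ca=x, cb=y) for x, y in zip(a, b)]
        assert sister_cycle_correlation(pairs) == pytest.approx(rho, abs=0.05)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        cycles = rng.normal(16, 3, size=(50, 2))
        pairs = [_pair(State.PROLIFERATING, State.PROLIFERATING, ca=x, cb=y) for x, y in cycles]
        swapped = [_pair(State.PROLIFERATING, State.PROLIFERATING, ca=y, cb=x) for x, y in cycles]
        assert sister_cycle_correlation(pairs) == pytest.approx(sister_cycle_correlation(swapped))

    def test_too_few_pairs_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sister_cycle_correlation([_pair(State.PROLIFERATING, State.PROLIFERATING, ca=10.0, cb=11.0)])
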