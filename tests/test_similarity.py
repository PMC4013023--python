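import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chorotypes.core_io import PresenceAbsenceTable
from chorotypes.similarity import (
    NullDistribution,
    PairCounts,
    bub_similarity,
    classify_pair,
    load_critical_values,
    null_distribution,
    pair_counts,
    significance_matrix,
    similarity_matrix,
)


class TestPairCounts:
    def test_simple_vectors(self):
        assert pair_counts([1, 1, 0, 0], [1, 0, 1, 0]) == PairCounts(1, 1, 1, 1)

    def test_identical_vectors_have_no_unique_presences(self):
        u = [1, 0, 1, 1, 0]
        c = pair_counts(u, u)
        assert (c.a, c.b) == (0, 0)
        assert c.n == 5

    def test_fixture_andes_vs_perija(self, pa):
        """Hand count over the 33 species: Serranía de Perijá's fauna is a
        strict subset of the Andean one."""
        frame = pa.to_frame()
        counts = pair_counts(frame["D1"], frame["D2"])
        assert counts == PairCounts(a=0, b=8, c=10, d=15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            pair_counts([1, 0], [1, 0, 1])


class TestBubSimilarity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (PairCounts(3, 2, 0, 7), 0.0),            # no shared presences
            (PairCounts(0, 0, 5, 10), 1.0),           # identical non-empty
            (PairCounts(0, 0, 5, 0), 1.0),
            # the Perijá/Andes pair: (sqrt(150)+10)/(sqrt(150)+18)
            (PairCounts(0, 8, 10, 15),
             (math.sqrt(150) + 10) / (math.sqrt(150) + 18)),
        ],
    )
    def test_values(self, counts, expected):
        assert bub_similarity(counts) == pytest.approx(expected, abs=1e-12)

    def test_two_empty_vectors_rejected(self):
        with pytest.raises(ValueError, match="empty vectors"):
            bub_similarity(PairCounts(0, 0, 0, 4))

    def test_monotone_in_shared_presences(self):
        """With n and both row totals fixed, the index never decreases as the
        overlap c grows — the basis for cumulative tail evaluation."""
        for n in (5, 10, 20, 33):
            for r1 in range(1, n + 1):
                for r2 in range(r1, n + 1):
                    values = []
                    for c in range(max(1, r1 + r2 - n), min(r1, r2) + 1):
                        values.append(bub_similarity(
                            PairCounts(r1 - c, r2 - c, c, n - r1 - r2 + c)))
                    assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))


class TestSimilarityMatrix:
    def test_q_mode_isolated_unit(self, q_result):
        """The Continental coast shares no species with any other unit."""
        frame = q_result.sim.to_frame()
        off = frame.loc["A2"].drop("A2")
        assert (off == 0.0).all()

    def test_r_mode_identical_ranges(self, r_result):
        frame = r_result.sim.to_frame()
        assert frame.loc["Marmosa tyleriana", "Monodelphis reigi"] == 1.0

    def test_symmetry_and_diagonal(self, q_result, r_result):
        for res in (q_result, r_result):
            v = res.sim.values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 1.0)
            assert v.min() >= 0.0 and v.max() <= 1.0


def brute_force_null(n: int) -> dict[float, float]:
    """Empirical null over all 4**n equiprobable attribute assignments."""
    out: dict[float, float] = {}
    weight = 1.0 / 4**n
    for cells in itertools.product(range(4), repeat=n):
        a = cells.count(0)
        b = cells.count(1)
        c = cells.count(2)
        d = n - a - b - c
        if c == 0:
            s = 0.0
        else:
            root = math.sqrt(c * d)
            s = (root + c) / (root + a + b + c)
        key = round(s, 12)
        out[key] = out.get(key, 0.0) + weight
    return out


class TestNullDistribution:
    def test_single_attribute(self):
        null = null_distribution(1)
        assert null.support.tolist() == [0.0, 1.0]
        # a, b or d cell -> 0 (the all-absent case maps to 0); c cell -> 1
        assert null.probabilities.tolist() == pytest.approx([0.75, 0.25])

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_enumeration_equals_brute_force(self, n):
        null = null_distribution(n)
        brute = brute_force_null(n)
        assert null.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(null.support) == len(brute)
        for s, p in zip(null.support, null.probabilities):
            assert p == pytest.approx(brute[round(float(s), 12)], abs=1e-12)

    def test_conditional_saturated_margins_are_degenerate(self):
        null = null_distribution(10, "conditional", r1=10, r2=10)
        assert null.support.tolist() == [1.0]

    def test_conditional_requires_margins(self):
        with pytest.raises(ValueError, match="requires r1 and r2"):
            null_distribution(10, "conditional")

    def test_monte_carlo_regime_close_to_exact(self):
        # just above the enumeration cutoff the sampled null should agree
        # with a directly enumerated one in both tails
        approx = null_distribution(61, n_monte_carlo=50_000, seed=3)
        assert approx.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert approx.upper_tail(1.0) < 0.01
        assert approx.lower_tail(0.0) < 0.01


class TestClassifyPair:
    def test_extremes_at_study_size(self):
        null = null_distribution(33)
        assert classify_pair(1.0, null) == 1
        assert classify_pair(0.0, null) == -1

    def test_degenerate_null_never_significant(self):
        null = NullDistribution(np.array([0.5]), np.array([1.0]), "conditional", 4)
        assert classify_pair(0.5, null) == 0

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=2, max_value=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antitone_in_alpha(self, s_obs, n):
        """Shrinking the significance level can only move a classification
        toward 0, never create one."""
        null = null_distribution(n)
        classes = [classify_pair(s_obs, null, alpha)
                   for alpha in (0.2, 0.1, 0.05, 0.01, 0.001)]
        signs = {c for c in classes if c != 0}
        assert len(signs) <= 1          # the direction never flips
        # once the classification drops to 0 it stays 0 at smaller alpha
        first_zero = classes.index(0) if 0 in classes else len(classes)
        assert all(c == 0 for c in classes[first_zero:])


class TestSignificanceMatrix:
    def test_isolated_unit_significantly_dissimilar(self, q_result):
        """All 14 pairs of the Continental coast classify as lower than
        random expectation under the exact null at n = 33."""
        frame = q_result.sig.to_frame()
        off = frame.loc["A2"].drop("A2")
        assert (off == -1).all()

    def test_identical_vectors_all_positive(self):
        cells = np.ones((5, 3), dtype=int)
        cells[0, 0] = 1
        table = PresenceAbsenceTable(tuple("abcde"), ("u1", "u2", "u3"), cells)
        sim = similarity_matrix(table, "Q")
        sig = significance_matrix(sim, table)
        off = sig.values[~np.eye(3, dtype=bool)]
        assert (off == 1).all()

    def test_tiny_alpha_turns_everything_off(self, pa, q_result):
        sig = significance_matrix(q_result.sim, pa, alpha=1e-15)
        assert (sig.values == 0).all()

    def test_invariant_to_label_order(self, pa, q_result):
        reordered = pa.to_frame().iloc[:, ::-1]
        table = PresenceAbsenceTable.from_frame(reordered)
        sim = similarity_matrix(table, "Q")
        sig = significance_matrix(sim, table)
        original = q_result.sig.to_frame()
        flipped = sig.to_frame().loc[list(original.index), list(original.columns)]
        assert (flipped.values == original.values).all()

    def test_symmetric(self, q_result, r_result):
        for res in (q_result, r_result):
            assert (res.sig.values == res.sig.values.T).all()

    def test_critical_value_table_scheme(self, pa, q_result, tmp_path):
        path = tmp_path / "crit.csv"
        path.write_text("n,lower,upper\n33,0.3,0.7\n")
        crit = load_critical_values(path)
        sig = significance_matrix(q_result.sim, pa, scheme="table",
                                  critical_values=crit)
        s = q_result.sim.to_frame()
        g = sig.to_frame()
        assert g.loc["A2", "B1"] == -1            # S = 0 < 0.3
        high = s.loc["D4", "D5"]
        assert high > 0.7 and g.loc["D4", "D5"] == 1
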