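import math

import numpy as np
import pytest
from scipy.stats import chi2, chi2_contingency

from chorotypes.boundaries import (
    Partition,
    ZoneCounts,
    boundary_report,
    dw_ds,
    extract_partition,
    g_test_yates,
    node_boundary,
    to_roman,
    zone_counts,
)
from chorotypes.clustering import upgma
from chorotypes.similarity import TrinarySignificanceMatrix


def random_sig(labels, seed):
    rng = np.random.default_rng(seed)
    k = len(labels)
    v = rng.choice([-1, 0, 1], size=(k, k))
    v = np.triu(v, 1)
    v = v + v.T
    return TrinarySignificanceMatrix(tuple(labels), v)


class TestZoneCounts:
    def test_singleton_group_has_no_within_pairs(self, q_result):
        rest = set(q_result.sig.labels) - {"A2"}
        c = zone_counts({"A2"}, rest, q_result.sig)
        assert (c.n_aa, c.p_aa, c.q_aa) == (0, 0, 0)
        assert c.n_ab == 14

    def test_isolated_unit_all_negative_across(self, q_result):
        rest = set(q_result.sig.labels) - {"A2"}
        c = zone_counts({"A2"}, rest, q_result.sig)
        assert c.q_ab == 14

    @pytest.mark.parametrize("seed", range(5))
    def test_zone_totals_conserve_all_pairs(self, seed):
        labels = [f"x{i}" for i in range(9)]
        sig = random_sig(labels, seed)
        rng = np.random.default_rng(seed + 100)
        cut = rng.integers(1, 8)
        a, b = set(labels[:cut]), set(labels[cut:])
        c = zone_counts(a, b, sig)
        m = len(labels)
        assert c.n_aa + c.n_bb + c.n_ab == m * (m - 1) // 2
        for zone in ("aa", "bb", "ab"):
            assert 0 <= getattr(c, f"p_{zone}") <= getattr(c, f"n_{zone}")
            assert 0 <= getattr(c, f"q_{zone}") <= getattr(c, f"n_{zone}")

    def test_sign_flip_swaps_count_families(self):
        labels = [f"x{i}" for i in range(8)]
        sig = random_sig(labels, 3)
        flipped = TrinarySignificanceMatrix(tuple(labels), -sig.values)
        a, b = set(labels[:3]), set(labels[3:])
        c1 = zone_counts(a, b, sig)
        c2 = zone_counts(a, b, flipped)
        assert (c1.p_aa, c1.p_bb, c1.p_ab) == (c2.q_aa, c2.q_bb, c2.q_ab)
        assert (c1.q_aa, c1.q_bb, c1.q_ab) == (c2.p_aa, c2.p_bb, c2.p_ab)

    def test_unknown_labels_rejected(self, q_result):
        with pytest.raises(KeyError, match="absent"):
            zone_counts({"A2"}, {"nope"}, q_result.sig)


class TestDwDs:
    def test_all_zero_counts(self):
        c = ZoneCounts(3, 3, 9, 0, 0, 0, 0, 0, 0)
        assert dw_ds(c) == (0.0, 0.0, 0.0, 0.0)

    def test_mean_aggregation_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(0, 10, 2)
            n_aa, n_bb = na * (na - 1) // 2, nb * (nb - 1) // 2
            n_ab = max(int(na * nb), 1)
            c = ZoneCounts(
                n_aa, n_bb, n_ab,
                rng.integers(0, n_aa + 1), rng.integers(0, n_bb + 1),
                rng.integers(0, n_ab + 1),
                rng.integers(0, n_aa + 1), rng.integers(0, n_bb + 1),
                rng.integers(0, n_ab + 1),
            )
            dw_aa, dw_bb, dw, ds = dw_ds(c)
            assert dw == pytest.approx((dw_aa + dw_bb) / 2, abs=1e-15)
            for v in (dw_aa, dw_bb, dw, ds):
                assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12

    def test_singleton_component_is_zero(self, q_result):
        rest = set(q_result.sig.labels) - {"A2"}
        c = zone_counts({"A2"}, rest, q_result.sig)
        dw_aa, *_ = dw_ds(c)
        assert dw_aa == 0.0


class TestGTestYates:
    def test_observed_equal_expected(self):
        assert g_test_yates(10, 10, 10, 10) == (0.0, 1.0)

    def test_perfect_association(self):
        G, p = g_test_yates(10, 0, 0, 10)
        # independent closed-form evaluation with the Yates-adjusted counts
        expected_G = 2 * (2 * 9.5 * math.log(9.5 / 5.0) + 2 * 0.5 * math.log(0.5 / 5.0))
        assert G == pytest.approx(expected_G, abs=1e-10)
        assert p < 0.001

    def test_zero_margin_carries_no_information(self):
        assert g_test_yates(0, 0, 5, 7) == (0.0, 1.0)
        assert g_test_yates(0, 5, 0, 7) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_uncorrected_and_correction_shrinks(self, seed):
        """For random tables the uncorrected G equals the closed form
        2 sum O ln(O/E) (cross-checked against scipy's log-likelihood-ratio
        test) and the Yates-adjusted G never exceeds it."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            k = rng.integers(1, 30, size=4)
            obs = np.array([[k[0], k[1]], [k[2], k[3]]], dtype=float)
            if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
                continue
            E = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                G_plain = 2 * np.where(obs > 0, obs * np.log(obs / E), 0.0).sum()
            G_scipy = chi2_contingency(obs, correction=False,
                                       lambda_="log-likelihood")[0]
            assert G_plain == pytest.approx(G_scipy, abs=1e-9)
            G_yates, p = g_test_yates(*k)
            assert G_yates <= G_plain + 1e-9
            assert p == pytest.approx(chi2.sf(G_yates, 1), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            g_test_yates(-1, 2, 3, 4)


class TestNodeBoundary:
    def test_fixture_south_vs_north_split(self, q_result):
        """The node separating the sub-regions south of the Orinoco from the
        northern ones shows both a weak and a strong boundary."""
        node = q_result.tree.node_by_members(frozenset(q_result.tree.leaves) - {"A2"})
        stats = node_boundary(node, q_result.sig)
        assert stats.boundary_class == "both"
        assert stats.gs == pytest.approx(8.109, abs=5e-3)

    def test_fixture_guayana_split_weak_only(self, r_result):
        members = frozenset({
            "Marmosa tyleriana", "Marmosops neblina", "Marmosops pakaraimae",
            "Monodelphis reigi", "Caluromys philander", "Monodelphis brevicaudata",
            "Didelphis imperfecta", "Lutreolina crassicaudata"})
        stats = node_boundary(r_result.tree.node_by_members(members), r_result.sig)
        assert stats.boundary_class == "weak"
        assert stats.gw == pytest.approx(16.228, abs=5e-3)
        assert stats.gs == 0.0 and stats.gs_stars == "n.s."

    def test_empty_significance_matrix_classifies_none(self, q_result):
        labels = q_result.sig.labels
        empty = TrinarySignificanceMatrix(labels, np.zeros((15, 15), dtype=int))
        stats = node_boundary(q_result.tree.root, empty)
        assert stats.boundary_class == "none"
        assert (stats.gw, stats.p_gw) == (0.0, 1.0)

    def test_zones_variant_runs(self, q_result):
        # use a node without singleton children so every zone has pairs
        node = q_result.tree.node_by_members(frozenset(q_result.tree.leaves) - {"A2"})
        stats = node_boundary(node, q_result.sig, contingency="zones")
        assert stats.gw > 0 and stats.gs > 0


class TestExtractPartition:
    def test_all_zero_matrix_yields_single_group(self, q_result):
        labels = q_result.sig.labels
        empty = TrinarySignificanceMatrix(labels, np.zeros((15, 15), dtype=int))
        part = extract_partition(q_result.tree, empty)
        assert len(part) == 1
        assert part.groups[0] == frozenset(labels)

    def test_fixture_biotic_regions(self, q_result):
        part = q_result.partition
        assert len(part) == 4
        assert part.group_of("A2") == "I"
        assert part.membership()["D7"] == "II"

    def test_fixture_chorotypes(self, r_result):
        part = r_result.partition
        assert len(part) == 11
        singletons = [g for g in part.groups if len(g) == 1]
        assert {next(iter(g)) for g in singletons} == {
            "Marmosa xerophila", "Marmosops cracens",
            "Monodelphis species A", "Philander deltae"}

    def test_partition_covers_leaves_disjointly(self, q_result, r_result):
        for res in (q_result, r_result):
            part = res.partition
            assert part.labels == frozenset(res.tree.leaves)
            assert sum(len(g) for g in part.groups) == len(res.tree.leaves)

    def test_invariant_to_leaf_order(self, pa):
        from chorotypes.core_io import PresenceAbsenceTable
        from chorotypes.pipeline import analyse_mode

        rng = np.random.default_rng(5)
        frame = pa.to_frame()
        shuffled = frame.iloc[:, rng.permutation(frame.shape[1])]
        res = analyse_mode(PresenceAbsenceTable.from_frame(shuffled), "Q")
        base = analyse_mode(pa, "Q")
        assert set(res.partition.groups) == set(base.partition.groups)


class TestBoundaryReport:
    def test_fixture_q_report_has_three_segregating_rows(self, q_result):
        sig_rows = q_result.report[q_result.report["boundary_class"] != "none"]
        assert len(sig_rows) == 3

    def test_r_report_contains_main_divide(self, r_result):
        """The split between the southern chorotypes and those north of the
        Orinoco sits at distance 0.857."""
        hits = r_result.report[
            (r_result.report["distance"] - 0.857).abs() < 5e-4]
        assert len(hits) == 1
        assert hits.iloc[0]["boundary_class"] == "both"

    def test_all_none_with_empty_sig(self, q_result):
        labels = q_result.sig.labels
        empty = TrinarySignificanceMatrix(labels, np.zeros((15, 15), dtype=int))
        report = boundary_report(q_result.tree, empty)
        assert (report["boundary_class"] == "none").all()


def test_roman_numerals():
    assert [to_roman(i) for i in (1, 4, 9, 11)] == ["I", "IV", "IX", "XI"]
    with pytest.raises(ValueError):
        to_roman(0)


def test_partition_rejects_overlap():
    with pytest.raises(ValueError, match="disjoint"):
        Partition((frozenset("ab"), frozenset("bc")), ("I", "II"))
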