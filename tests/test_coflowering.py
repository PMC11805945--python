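"""Co-flowering overlap algebra, change matrix, guild masks, rank order."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoshift.coflowering import (
    ChangeKind,
    FloweringInterval,
    change_cell,
    change_matrix,
    coflowering_matrix,
    competitor_summary,
    count_change_categories,
    interval_overlap_days,
    rank_order_change,
    shared_pollinator_mask,
    ternary_matrix,
    ternary_reduce,
)
from phenoshift.io import GuildEntry
from phenoshift.phenometrics import SpeciesDecadePhenology


def iv(name, s, e):
    return FloweringInterval(name, s, e)


doy = st.integers(min_value=1, max_value=365)


class TestOverlap:
    def test_identical_intervals(self):
        a = iv("a", 10, 20)
        assert interval_overlap_days(a, iv("b", 10, 20)) == a.flowering_days == 11

    def test_disjoint_arcs(self):
        assert interval_overlap_days(iv("a", 10, 20), iv("b", 100, 150)) == 0

    def test_wrap_against_plain(self):
        # arc 350..30 meets arc 10..60 exactly on days 10..30
        assert interval_overlap_days(iv("a", 350, 30), iv("b", 10, 60)) == 21

    @given(doy, doy, doy, doy)
    @settings(max_examples=200, deadline=None)
    def test_matches_day_set_oracle(self, s1, e1, s2, e2):
        a, b = iv("a", s1, e1), iv("b", s2, e2)
        oracle = len(a.day_set() & b.day_set())
        assert interval_overlap_days(a, b) == oracle
        assert interval_overlap_days(b, a) == oracle

    @given(doy, doy)
    @settings(max_examples=100, deadline=None)
    def test_flowering_days_matches_day_set(self, s, e):
        a = iv("a", s, e)
        assert a.flowering_days == len(a.day_set())


class TestMatrix:
    def test_nested_intervals(self):
        mat, labels = coflowering_matrix([iv("A", 100, 110), iv("B", 90, 130)])
        i, j = labels.index("A"), labels.index("B")
        assert mat[i, j] == 1.0  # A fully inside B
        assert mat[j, i] == pytest.approx(11 / 41)

    def test_no_overlap_off_diagonals_zero(self):
        mat, _ = coflowering_matrix([iv("A", 10, 20), iv("B", 200, 210)])
        assert mat[0, 1] == 0.0 and mat[1, 0] == 0.0
        assert mat[0, 0] == mat[1, 1] == 1.0

    def test_reciprocity_identity_random_intervals(self, rng):
        for _ in range(50):
            ivs = [
                iv(f"s{k}", int(rng.integers(1, 366)), int(rng.integers(1, 366)))
                for k in range(6)
            ]
            mat, _ = coflowering_matrix(ivs)
            for i in range(6):
                for j in range(6):
                    shared_ij = mat[i, j] * ivs[i].flowering_days
                    shared_ji = mat[j, i] * ivs[j].flowering_days
                    assert shared_ij == pytest.approx(shared_ji, abs=1e-9)
                    assert round(shared_ij) == pytest.approx(shared_ij, abs=1e-9)


class TestChangeCell:
    def test_doubling_gives_two(self):
        cell = change_cell(0.2, 0.4)
        assert cell.kind is ChangeKind.FOLD and cell.fold_value == pytest.approx(2.0)

    def test_halving_gives_minus_half(self):
        cell = change_cell(0.4, 0.2)
        assert cell.fold_value == pytest.approx(-0.5)

    def test_no_change_gives_one(self):
        assert change_cell(0.3, 0.3).fold_value == pytest.approx(1.0)

    def test_gain_loss_none(self):
        assert change_cell(0.0, 0.25).kind is ChangeKind.GAIN
        assert change_cell(0.25, 0.0).kind is ChangeKind.LOSS
        assert change_cell(0.0, 0.0).kind is ChangeKind.NONE

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            change_cell(1.2, 0.5)

    def test_alternative_decrease_convention(self):
        # -1/rho encoding: a drop to a quarter scores -4 instead of -0.25
        cell = change_cell(0.4, 0.1, decrease_convention="neg_inv_rho")
        assert cell.fold_value == pytest.approx(-4.0)
        # halving: -2 under the symmetric convention vs -0.5 under the default
        assert change_cell(0.4, 0.2, decrease_convention="neg_inv_rho").fold_value == \
            pytest.approx(-2.0)
        with pytest.raises(ValueError, match="convention"):
            change_cell(0.4, 0.2, decrease_convention="bogus")

    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_swap_antisymmetry(self, p, q):
        fwd, back = change_cell(p, q), change_cell(q, p)
        if q > p:
            assert fwd.fold_value == pytest.approx(q / p)
            assert back.fold_value == pytest.approx(-p / q)
        values = (fwd.fold_value, back.fold_value)
        assert (values[0] >= 1) != (values[1] >= 1) or p == q

    @given(
        st.floats(min_value=0.01, max_value=0.5),
        st.floats(min_value=0.01, max_value=0.5),
        st.floats(min_value=0.1, max_value=2.0),
    )
    def test_ternary_scale_invariance(self, p, q, c):
        if p * c <= 1 and q * c <= 1:
            assert ternary_reduce(change_cell(p, q)) == ternary_reduce(
                change_cell(p * c, q * c)
            )


class TestCategories:
    def test_identical_matrices_all_unchanged(self):
        mat = np.array([[1.0, 0.5, 0.2], [0.4, 1.0, 0.1], [0.3, 0.2, 1.0]])
        counts = count_change_categories(change_matrix(mat, mat.copy()))
        assert counts["n_increased"] == counts["n_decreased"] == 0
        assert counts["n_unchanged"] == 6

    def test_three_species_toy_hand_enumeration(self):
        old = np.array([[1.0, 0.2, 0.0], [0.1, 1.0, 0.4], [0.0, 0.3, 1.0]])
        new = np.array([[1.0, 0.4, 0.2], [0.1, 1.0, 0.2], [0.1, 0.3, 1.0]])
        counts = count_change_categories(change_matrix(old, new))
        # hand count over the 6 off-diagonal cells:
        # (0,1) 0.2->0.4 doubled; (0,2) gain; (1,0) unchanged; (1,2) halved;
        # (2,0) gain; (2,1) unchanged
        assert counts == {
            "n_increased": 3, "n_decreased": 1, "n_gain": 2, "n_loss": 0,
            "n_unchanged": 2, "n_none": 0,
        }

    def test_partition_identity(self, rng):
        n = 7
        old = rng.random((n, n)) * (rng.random((n, n)) > 0.3)
        new = rng.random((n, n)) * (rng.random((n, n)) > 0.3)
        np.fill_diagonal(old, 1.0)
        np.fill_diagonal(new, 1.0)
        c = count_change_categories(change_matrix(old, new))
        assert (
            c["n_increased"] + c["n_decreased"] + c["n_unchanged"] + c["n_none"]
            == n * (n - 1)
        )


class TestGuildMask:
    guilds = [
        GuildEntry("bee1", frozenset({"small bees", "hoverflies"}), False),
        GuildEntry("bee2", frozenset({"small bees", "medium bees"}), False),
        GuildEntry("lone", frozenset({"very small flies"}), False),
        GuildEntry("windy", frozenset(), True),
    ]
    labels = ["bee1", "bee2", "lone", "windy"]

    def test_shared_agents_true(self):
        mask = shared_pollinator_mask(self.guilds, self.labels)
        assert mask[0, 1] and mask[1, 0]

    def test_unique_token_shares_with_none(self):
        mask = shared_pollinator_mask(self.guilds, self.labels)
        assert not mask[2, :].any() and not mask[:, 2].any()

    def test_wind_excluded_entirely(self):
        mask = shared_pollinator_mask(self.guilds, self.labels)
        assert not mask[3, :].any() and not mask[:, 3].any()

    def test_missing_species_is_error(self):
        with pytest.raises(KeyError, match="ghost"):
            shared_pollinator_mask(self.guilds, self.labels + ["ghost"])


class TestCompetitorSummary:
    def test_toy_brute_force(self):
        ternary = np.array([[0, 1, -1], [1, 0, 1], [-1, 1, 0]])
        mask = np.array(
            [[False, True, True], [True, False, False], [True, False, False]]
        )
        summary = competitor_summary(ternary, mask, ["a", "b", "c"])
        assert summary.per_species == {"a": 0, "b": 1, "c": -1}
        assert summary.total == 0
        assert summary.total == sum(summary.per_species.values())

    def test_all_zero_ternary(self):
        z = np.zeros((3, 3), dtype=int)
        summary = competitor_summary(z, np.ones((3, 3), bool), ["a", "b", "c"])
        assert set(summary.per_species.values()) == {0}

    def test_wind_species_excluded_from_rows(self):
        guilds = [
            GuildEntry("a", frozenset({"small bees"}), False),
            GuildEntry("w", frozenset(), True),
        ]
        ternary = np.array([[0, 1], [1, 0]])
        mask = shared_pollinator_mask(guilds, ["a", "w"])
        summary = competitor_summary(ternary, mask, ["a", "w"], guilds)
        assert "w" not in summary.per_species
        assert summary.excluded_wind == ["w"]


def sp_phen(name, start, decade="d"):
    return SpeciesDecadePhenology(name, decade, start, 1.0, start + 30, 1.0,
                                  start + 15, 30.0, 5)


class TestRankOrder:
    def test_identical_decades_zero_delta(self):
        phens = [sp_phen("a", 50), sp_phen("b", 90), sp_phen("c", 140)]
        table = rank_order_change(phens, phens)
        assert (table["delta_rank"] == 0).all()
        assert sorted(table["rank_ref"]) == [1, 2, 3]

    def test_leapfrog(self):
        ref = [sp_phen("A", 50), sp_phen("B", 90)]
        new = [sp_phen("A", 80), sp_phen("B", 40)]
        table = rank_order_change(ref, new).set_index("species_id")
        assert table.loc["B", "delta_rank"] == -1
        assert table.loc["A", "delta_rank"] == 1

    def test_ranks_are_permutations(self, rng):
        names = [f"s{i}" for i in range(10)]
        ref = [sp_phen(n, int(rng.integers(1, 360))) for n in names]
        new = [sp_phen(n, int(rng.integers(1, 360))) for n in names]
        table = rank_order_change(ref, new)
        assert sorted(table["rank_ref"]) == list(range(1, 11))
        assert sorted(table["rank_new"]) == list(range(1, 11))
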