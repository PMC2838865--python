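"""Transcript grouping rules, the 15% reliability gate and the recursion."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from spotcall import (
    DyeSwapFlag,
    GroupingError,
    Regulation,
    group_est_set,
    group_two_ests,
    pooled_relative_error,
)
from tests.conftest import make_ds

ABSENT = DyeSwapFlag.ABSENT
NON_REG = DyeSwapFlag.NON_REGULATED
NON_REL = DyeSwapFlag.NON_RELIABLE
TRUE = DyeSwapFlag.TRUE
UP, DOWN, NONE = Regulation.UP, Regulation.DOWN, Regulation.NONE


def rule_table_oracle(flag_a, dir_a, flag_b, dir_b, rel_err, threshold=15.0):
    """Literal transcription of the two-EST grouping table.

    Returns (flag, value_kind, regulation) where value_kind is "zero"
    or "average".
    """
    flags = {flag_a, flag_b}
    if flags == {ABSENT}:
        return ABSENT, "zero", NONE
    if TRUE in flags:
        if flags == {TRUE}:
            dirs = {dir_a, dir_b}
            if dirs == {UP} or dirs == {DOWN}:
                direction = dir_a
                if rel_err <= threshold:
                    return TRUE, "average", direction
                return NON_REL, "average", direction
            return NON_REL, "average", NONE
        return NON_REL, "average", NONE
    if flags == {NON_REG}:
        return NON_REG, "average", NONE
    return NON_REL, "zero", NONE


def member_states():
    # replicate multisets realizing a low (~7%) and a high (~25%)
    # relative-error regime once pooled with a same-direction partner
    yield ABSENT, NONE, math.nan, ()
    yield NON_REG, NONE, 1.05, (1.0, 1.1)
    yield NON_REL, NONE, 1.4, (1.2, 1.6)
    for d, r in ((UP, 2.0), (DOWN, 0.5)):
        yield TRUE, d, r, (r * 0.95, r * 1.05)  # tight replicates
        yield TRUE, d, r, (r * 0.7, r * 1.3)  # scattered replicates


class TestTwoESTRules:
    def test_exhaustive_ordered_pairs_match_rule_table(self):
        count = 0
        for (fa, da, ra, reps_a), (fb, db, rb, reps_b) in itertools.product(
            member_states(), member_states()
        ):
            a = make_ds(fa, da, ra, clone="C1", replicates=reps_a)
            b = make_ds(fb, db, rb, clone="C2", replicates=reps_b)
            out = group_two_ests(a, b)
            rel_err = pooled_relative_error(reps_a + reps_b)
            exp_flag, value_kind, exp_reg = rule_table_oracle(fa, da, fb, db, rel_err)
            assert out.final_flag is exp_flag, (fa, da, fb, db)
            assert out.regulation is exp_reg, (fa, da, fb, db)
            defined = [r for r in (ra, rb) if math.isfinite(r)]
            if value_kind == "zero":
                assert out.value == 0.0
            else:
                assert out.value == pytest.approx(float(np.mean(defined)))
            count += 1
        assert count == 49

    def test_documented_rows(self):
        # both TRUE UP with agreeing replicates -> TRUE, average, UP
        a = make_ds(TRUE, UP, 2.0, clone="C1", replicates=(1.9, 2.1))
        b = make_ds(TRUE, UP, 2.2, clone="C2", replicates=(2.1, 2.3))
        out = group_two_ests(a, b)
        assert out.final_flag is TRUE
        assert out.value == pytest.approx(2.1)
        assert out.regulation is UP
        # absent + absent -> absent, 0, NONE
        out = group_two_ests(
            make_ds(ABSENT, NONE, math.nan, clone="C1"),
            make_ds(ABSENT, NONE, math.nan, clone="C2"),
        )
        assert (out.final_flag, out.value, out.regulation) == (ABSENT, 0.0, NONE)
        # opposite directions -> non reliable, average, NONE
        out = group_two_ests(
            make_ds(TRUE, UP, 2.0, clone="C1"),
            make_ds(TRUE, DOWN, 0.5, clone="C2"),
        )
        assert out.final_flag is NON_REL
        assert out.value == pytest.approx(1.25)
        assert out.regulation is NONE

    def test_relative_error_gate_and_boundary(self):
        # scattered replicates: rel err > 15 -> non reliable but keeps direction
        a = make_ds(TRUE, UP, 2.0, clone="C1", replicates=(1.4, 2.6))
        b = make_ds(TRUE, UP, 2.0, clone="C2", replicates=(1.4, 2.6))
        out = group_two_ests(a, b)
        assert out.relative_error > 15.0
        assert out.final_flag is NON_REL
        assert out.regulation is UP
        # exactly at the threshold the grouping still passes (gate is strict >)
        rel = pooled_relative_error((1.4, 2.6) * 2)
        out = group_two_ests(a, b, rel_error_threshold=rel)
        assert out.final_flag is TRUE

    def test_gene_mismatch_raises(self):
        with pytest.raises(GroupingError):
            group_two_ests(
                make_ds(TRUE, UP, 2.0, gene="G1"),
                make_ds(TRUE, UP, 2.0, gene="G2"),
            )


class TestESTSetGrouping:
    def test_single_member_promotion(self):
        t = group_est_set([make_ds(TRUE, UP, 2.0)])
        assert (t.final_flag, t.value, t.regulation) == (TRUE, 2.0, UP)
        t = group_est_set([make_ds(ABSENT, NONE, math.nan)])
        assert (t.final_flag, t.value, t.regulation) == (ABSENT, 0.0, NONE)

    @pytest.mark.parametrize("k", range(1, 7))
    def test_identical_true_members_are_idempotent(self, k):
        members = [
            make_ds(TRUE, UP, 2.0, clone=f"C{i}", replicates=(2.0, 2.0))
            for i in range(k)
        ]
        t = group_est_set(members)
        assert t.final_flag is TRUE
        assert t.value == pytest.approx(2.0, rel=1e-12)
        assert t.regulation is UP
        assert t.relative_error == 0.0

    def test_fold_with_absent_member_degrades_to_non_reliable(self):
        members = [
            make_ds(TRUE, UP, 2.0, clone="C1"),
            make_ds(TRUE, UP, 2.0, clone="C2"),
            make_ds(ABSENT, NONE, math.nan, clone="C3"),
        ]
        t = group_est_set(members)
        assert t.final_flag is NON_REL
        assert t.regulation is NONE

    def test_member_clones_conserved_in_order(self):
        members = [
            make_ds(TRUE, UP, 2.0, clone=c) for c in ("C3", "C1", "C2")
        ]
        t = group_est_set(members)
        assert t.member_clones == ("C3", "C1", "C2")
        t = group_est_set(members, sort_members=True)
        assert t.member_clones == ("C1", "C2", "C3")

    def test_deterministic_for_fixed_order(self):
        members = [
            make_ds(TRUE, UP, 1.8 + 0.1 * i, clone=f"C{i}", replicates=(1.8, 2.2))
            for i in range(4)
        ]
        t1 = group_est_set(members)
        t2 = group_est_set(members)
        assert t1 == t2

    def test_empty_member_list_raises(self):
        with pytest.raises(GroupingError):
            group_est_set([])

    def test_more_than_six_members_warns(self):
        members = [make_ds(TRUE, UP, 2.0, clone=f"C{i}") for i in range(7)]
        with pytest.warns(UserWarning, match="ESTs"):
            group_est_set(members)
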