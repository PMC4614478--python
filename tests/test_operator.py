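"""Error injection, noticing, canonical repairs and full entry trials."""

import random
from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

from numentry import (
    DESIGN_IDS,
    ErrorClass,
    ErrorEvent,
    ErrorModel,
    Key,
    OperatorParams,
    TargetDistribution,
    TargetNumber,
    encode_number,
    inject_and_type,
    repair_plan,
    simulate_entry,
)


def ev(cls, pos, planned, realized, noticed=True):
    to_keys = lambda s: tuple(Key(c) for c in s)
    return ErrorEvent(cls, pos, to_keys(planned), to_keys(realized), noticed)


class TestRepairPlan:
    @pytest.mark.parametrize(
        "event, plan",
        [
            (ev(ErrorClass.REPETITION, 0, "5", "55"), [Key.DELETE]),
            (ev(ErrorClass.OMISSION, 1, ".", ""), [Key.POINT]),
            (
                ev(ErrorClass.TRANSPOSITION, 0, "25", "52"),
                [Key.DELETE, Key.DELETE, Key.D2, Key.D5],
            ),
            (ev(ErrorClass.SUBSTITUTION, 0, "2", "7"), [Key.DELETE, Key.D2]),
            (ev(ErrorClass.INSERTION, 0, "2", "2."), [Key.DELETE]),
        ],
    )
    def test_canonical_repairs(self, event, plan):
        assert repair_plan(event) == plan

    def test_clear_only_design_replans_everything(self):
        planned = [Key.D1, Key.D0, Key.D0]
        e = ev(ErrorClass.REPETITION, 1, "0", "00")
        assert repair_plan(e, design="N", planned=planned) == [Key.CLEAR, *planned]


class TestEventInvariants:
    def test_substitution_must_change_the_key(self):
        with pytest.raises(ValueError):
            ev(ErrorClass.SUBSTITUTION, 0, "2", "2")

    def test_transposition_needs_two_keys(self):
        with pytest.raises(ValueError):
            ev(ErrorClass.TRANSPOSITION, 0, "2", "52")

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            OperatorParams(vulnerability=1.5)
        with pytest.raises(ValueError):
            OperatorParams(per_class_error_prob=0.3)  # five classes sum > 1
        with pytest.raises(ValueError):
            ErrorModel(max_attempts=0)


class TestInjectAndType:
    def test_no_errors_means_verbatim_typing(self):
        rng = random.Random(0)
        params = OperatorParams(per_class_error_prob=0.0, vulnerability=0.3)
        for design in DESIGN_IDS:
            planned = encode_number(TargetNumber.from_string("40.5"))
            trial = inject_and_type(design, planned, params, rng)
            assert list(trial.realized_keys) == planned
            assert trial.harm == 0 and trial.n_errors == 0

    def test_fully_vulnerable_operator_never_repairs(self):
        params = OperatorParams(per_class_error_prob=0.1, vulnerability=1.0)
        rng = random.Random(5)
        dist = TargetDistribution()
        for _ in range(100):
            planned = encode_number(dist.draw(rng))
            trial = inject_and_type("C", planned, params, rng)
            assert Key.DELETE not in trial.realized_keys
            assert Key.CLEAR not in trial.realized_keys
            assert all(not e.noticed for e in trial.events)

    def test_fully_careful_operator_notices_everything(self):
        params = OperatorParams(per_class_error_prob=0.1, vulnerability=0.0)
        rng = random.Random(6)
        for _ in range(100):
            planned = encode_number(TargetDistribution().draw(rng))
            trial = inject_and_type("C", planned, params, rng)
            assert all(e.noticed for e in trial.events)
            assert trial.harm == 0  # correct design repairs always restore

    def test_planned_sequence_must_be_clean(self):
        with pytest.raises(ValueError):
            inject_and_type(
                "C", [Key.D1, Key.DELETE], OperatorParams(), random.Random(0)
            )


class TestSimulateEntry:
    def test_deterministic_given_seed(self):
        params = OperatorParams(per_class_error_prob=0.05, vulnerability=0.5)
        t = TargetNumber.from_string("2.5")
        a = simulate_entry("E", t, params, random.Random(123), record=True)
        b = simulate_entry("E", t, params, random.Random(123), record=True)
        assert a.realized_keys == b.realized_keys
        assert (a.final_value, a.harm, a.attempts) == (b.final_value, b.harm, b.attempts)

    def test_error_free_transparency_across_designs(self):
        # with no typing errors every design accepts the intended value;
        # the debounced design needs one confirmation re-entry on repeats
        params = OperatorParams(per_class_error_prob=0.0, vulnerability=1.0)
        rng = random.Random(7)
        dist = TargetDistribution()
        for _ in range(200):
            target = dist.draw(rng)
            has_repeat = any(
                a == b for a, b in zip(target.canonical, target.canonical[1:])
            )
            for design in DESIGN_IDS:
                trial = simulate_entry(design, target, params, rng)
                assert trial.harm == 0, (design, target.canonical)
                assert trial.final_value == target.value
                if design == "D":
                    assert trial.attempts == (2 if has_repeat else 1)
                else:
                    assert trial.attempts == 1

    def test_careful_operator_on_checked_designs_never_harmed(self):
        params = OperatorParams(per_class_error_prob=0.02, vulnerability=0.0)
        rng = random.Random(8)
        dist = TargetDistribution()
        for _ in range(500):
            target = dist.draw(rng)
            for design in ("C", "D", "E", "F", "G", "N"):
                assert simulate_entry(design, target, params, rng).harm == 0

    def test_optimal_ismp_design_fixes_all_rejections(self):
        # once design F rejects, the retype is flawless: final == intended
        params = OperatorParams(per_class_error_prob=0.05, vulnerability=1.0)
        rng = random.Random(9)
        dist = TargetDistribution()
        rejected = 0
        for _ in range(500):
            target = dist.draw(rng)
            trial = simulate_entry("F", target, params, rng)
            if trial.attempts > 1:
                rejected += 1
                assert trial.final_value == target.value and trial.harm == 0
        assert rejected > 0  # the scenario actually exercised re-entry

    def test_range_check_accepts_only_within_factor_five(self):
        params = OperatorParams(per_class_error_prob=0.05, vulnerability=1.0)
        rng = random.Random(10)
        t = TargetNumber.from_string("10")
        for _ in range(300):
            trial = simulate_entry("G", t, params, rng)
            if trial.capped:
                continue
            v = trial.final_value
            assert v != 0 and max(v, 10) / min(v, 10) < 5

    def test_identical_streams_make_uncheckable_designs_agree(self):
        # at v=1 with digit-only substitutions, A, B, C and N process the
        # same realized keys and store the same string
        params = OperatorParams(
            class_probs=(0, 0, 0, 0.1, 0),
            substitution_alphabet="0123456789",
            vulnerability=1.0,
        )
        dist = TargetDistribution()
        for i in range(200):
            target = dist.draw(random.Random(1000 + i))
            finals = set()
            for design in ("A", "B", "C", "N"):
                rng = random.Random(2000 + i)
                trial = simulate_entry(design, target, rng=rng, params=params)
                finals.add(str(trial.final_value))
            assert len(finals) == 1


@given(st.integers(0, 10_000))
def test_harm_is_exact_value_mismatch(seed):
    params = OperatorParams(per_class_error_prob=0.05, vulnerability=0.7)
    rng = random.Random(seed)
    target = TargetDistribution().draw(rng)
    trial = simulate_entry("C", target, params, rng)
    if not trial.capped:
        assert trial.harm == (0 if trial.final_value == target.value else 1)
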