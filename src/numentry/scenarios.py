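"""Deterministic keystroke scenarios: curated pathologies and bulk fixtures.

A :class:`Scenario` scripts one number entry completely — intended value,
error events with their positions, realized keys and noticing flags — so
replaying it through the operator model and a design is deterministic.
The curated :func:`pathology_suite` materializes the classic failure
modes of the commercial designs (delete reaching past a decimal point,
the silently ignored second point, clear-and-retype recovery, double
entry of repeated digits, notation and range interception) as executable
examples.  :func:`random_scenarios` generates bulk fixtures whose
expectations are computed by the naive reference interpreter and an
independent submission-rule re-implementation — never by the simulator
under test — so the fixture suite doubles as a differential test.

In every scenario, re-entry attempts forced by a design rejection are
replayed flawlessly (the scripted events concern the first attempt only).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Optional, Sequence, Union

from .codec import INVALID, TargetNumber, encode_number, value_of, _Invalid
from .designs import DESIGN_IDS, _submit_stored
from .keys import Key
from .operator import EntryTrial, ErrorClass, ErrorEvent, replay_attempt

_MAX_REPLAY_ATTEMPTS = 5


@dataclass(frozen=True)
class Scenario:
    """A fully scripted entry with its oracle-derived expectation."""

    name: str
    design: str
    intended: TargetNumber
    scripted_events: tuple[ErrorEvent, ...]
    expected_final: Union[Decimal, _Invalid]
    expected_harm: int


def replay_scenario(sc: Scenario) -> EntryTrial:
    """Replay a scenario through the operator model and design machinery."""
    planned = encode_number(sc.intended)
    canonical = sc.intended.canonical
    all_keys: list[Key] = []
    last_sub: Optional[str] = None
    for attempt in range(1, _MAX_REPLAY_ATTEMPTS + 1):
        if attempt == 1:
            stored, realized = replay_attempt(sc.design, planned, sc.scripted_events)
        else:
            stored, realized = canonical, list(planned)
            all_keys.append(Key.CLEAR)
        all_keys.extend(realized)
        all_keys.append(Key.ENTER)
        accepted, _, last_sub = _submit_stored(
            sc.design, stored, sc.intended, last_sub
        )
        if accepted:
            val = value_of(stored)
            return EntryTrial(
                sc.intended,
                sc.design,
                tuple(all_keys),
                sc.scripted_events,
                val,
                0 if val == sc.intended.value else 1,
                attempt,
            )
    raise RuntimeError(f"scenario {sc.name!r} did not settle while replaying")


# ---------------------------------------------------------------------------
# Independent expectation oracle (naive, separate from the simulator)

_ISMP_RE = re.compile(r"(0|[1-9][0-9]*)(\.[0-9]*[1-9])?")


def _naive_fraction(s: str) -> Optional[Fraction]:
    if s.count(".") >= 2:
        return None
    ipart, _, fpart = s.partition(".")
    scale = 10 ** len(fpart)
    return Fraction(int(ipart or 0) * scale + int(fpart or 0), scale)


def _naive_realized(design: str, planned: Sequence[Key], events) -> list[Key]:
    """Realized key log from scripted events, coded independently."""
    by_pos = {e.position: e for e in events}
    keys: list[Key] = []
    i = 0
    while i < len(planned):
        e = by_pos.get(i)
        if e is None:
            keys.append(planned[i])
            i += 1
            continue
        keys.extend(e.realized_tokens)
        step = 2 if e.error_class is ErrorClass.TRANSPOSITION else 1
        if e.noticed:
            if design == "N":
                keys.append(Key.CLEAR)
                keys.extend(planned)
                return keys
            cls = e.error_class
            if cls is ErrorClass.OMISSION:
                keys.append(planned[i])
            elif cls is ErrorClass.SUBSTITUTION:
                keys.extend([Key.DELETE, planned[i]])
            elif cls is ErrorClass.TRANSPOSITION:
                keys.extend([Key.DELETE, Key.DELETE, planned[i], planned[i + 1]])
            else:  # repetition, insertion
                keys.append(Key.DELETE)
        i += step
    return keys


def _naive_rejects(design: str, stored: str, target: TargetNumber) -> bool:
    """First-submission accept/reject, re-implemented naively."""
    if design in ("A", "B"):
        return False
    if stored.count(".") >= 2:
        return True
    if design == "D":
        return any(a == b for a, b in zip(stored, stored[1:]))
    if design in ("E", "F"):
        return _ISMP_RE.fullmatch(stored) is None
    if design == "G":
        got = _naive_fraction(stored)
        want = _naive_fraction(target.canonical)
        if (got == 0) != (want == 0):
            return True
        if got != 0 and max(got, want) >= 5 * min(got, want):
            return True
    return False


def oracle_expectation(
    design: str, intended: TargetNumber, events: Sequence[ErrorEvent]
) -> tuple[Union[Decimal, _Invalid], int]:
    """Expected final value and harm, via the reference interpreter only."""
    from .designs import reference_interpreter

    planned = encode_number(intended)
    realized = _naive_realized(design, planned, events)
    stored = reference_interpreter(design, realized)
    if _naive_rejects(design, stored, intended):
        # every re-entry is flawless in scenario replay, so the design's
        # rejection loop always settles on the canonical rendering
        stored = intended.canonical
    frac = _naive_fraction(stored)
    if frac is None:
        return INVALID, 1
    final = Decimal(frac.numerator) / Decimal(frac.denominator)
    harm = 0 if frac == _naive_fraction(intended.canonical) else 1
    return final, harm


# ---------------------------------------------------------------------------
# Curated pathology suite


def _ev(cls, pos, planned, realized, noticed) -> ErrorEvent:
    as_keys = lambda s: tuple(Key(c) for c in s)
    return ErrorEvent(cls, pos, as_keys(planned), as_keys(realized), noticed)


def pathology_suite() -> list[Scenario]:
    """Named scenarios reproducing the designs' characteristic behaviours.

    Expected values are hand-derived from the design semantics; the test
    suite cross-checks every one against the reference-interpreter oracle.
    """
    t = TargetNumber.from_string
    R, O, T, S, I = (
        ErrorClass.REPETITION,
        ErrorClass.OMISSION,
        ErrorClass.TRANSPOSITION,
        ErrorClass.SUBSTITUTION,
        ErrorClass.INSERTION,
    )
    scenarios = [
        # design A's delete only removes digits: repairing a noticed point
        # insertion deletes the digit before the point instead
        Scenario("A-noticed-point-insertion-misrepairs", "A", t("23"),
                 (_ev(I, 0, "2", "2.", True),), Decimal("0.3"), 1),
        Scenario("C-noticed-point-insertion-repairs", "C", t("23"),
                 (_ev(I, 0, "2", "2.", True),), Decimal("23"), 0),
        # A ignores a repeated point outright — here that is harmless
        Scenario("A-ignored-second-point-is-harmless", "A", t("1.5"),
                 (_ev(R, 1, ".", "..", False),), Decimal("1.5"), 0),
        # B ignored the second point, so the repairing delete removes the
        # real point the operator wanted to keep
        Scenario("B-ignored-point-delete-surprise", "B", t("1.5"),
                 (_ev(R, 1, ".", "..", True),), Decimal("15"), 1),
        Scenario("C-second-point-delete-recovers", "C", t("1.5"),
                 (_ev(R, 1, ".", "..", True),), Decimal("1.5"), 0),
        # repairing a transposition on A deletes digits across the point
        Scenario("A-transposition-repair-deletes-past-point", "A", t("2.5"),
                 (_ev(T, 1, ".5", "5.", True),), Decimal("0.5"), 1),
        Scenario("C-transposition-repair-recovers", "C", t("2.5"),
                 (_ev(T, 1, ".5", "5.", True),), Decimal("2.5"), 0),
        # ISMP notation interception: a trailing zero reveals the error
        Scenario("E-rejects-trailing-zero-error", "E", t("2.5"),
                 (_ev(S, 2, "5", "0", False),), Decimal("2.5"), 0),
        Scenario("C-accepts-trailing-zero-error", "C", t("2.5"),
                 (_ev(S, 2, "5", "0", False),), Decimal("2.0"), 1),
        # dose-error-reduction range check blocks a tenfold error
        Scenario("G-range-blocks-tenfold-omission", "G", t("1.5"),
                 (_ev(O, 1, ".", "", False),), Decimal("1.5"), 0),
        Scenario("C-accepts-tenfold-omission", "C", t("1.5"),
                 (_ev(O, 1, ".", "", False),), Decimal("15"), 1),
        # N's clear-and-retype also erases an earlier unnoticed error
        Scenario("N-clear-retype-erases-unnoticed-error", "N", t("123"),
                 (_ev(S, 0, "1", "7", False), _ev(S, 1, "2", "5", True)),
                 Decimal("123"), 0),
        Scenario("C-keeps-earlier-unnoticed-error", "C", t("123"),
                 (_ev(S, 0, "1", "7", False), _ev(S, 1, "2", "5", True)),
                 Decimal("723"), 1),
        # D needs intended repeats entered twice, and blocks key bounce
        Scenario("D-intended-repeat-needs-double-entry", "D", t("100"),
                 (), Decimal("100"), 0),
        Scenario("D-blocks-key-bounce", "D", t("15"),
                 (_ev(R, 1, "5", "55", False),), Decimal("15"), 0),
        Scenario("C-accepts-key-bounce", "C", t("15"),
                 (_ev(R, 1, "5", "55", False),), Decimal("155"), 1),
    ]
    return scenarios


# ---------------------------------------------------------------------------
# Bulk random fixtures


def random_scenarios(count: int, seed: int) -> list[Scenario]:
    """Deterministic random scenarios with oracle-computed expectations."""
    if count < 1:
        raise ValueError("count must be >= 1")
    from .codec import TargetDistribution
    from .keys import ALPHABET_CHARS as ALPHA

    rng = random.Random(seed)
    dist = TargetDistribution()
    out = []
    for idx in range(count):
        design = DESIGN_IDS[rng.randrange(len(DESIGN_IDS))]
        intended = dist.draw(rng)
        planned = encode_number(intended)
        events = []
        i = 0
        while i < len(planned):
            if rng.random() >= 0.15:
                i += 1
                continue
            choices = list(ErrorClass)
            if i == len(planned) - 1:
                choices.remove(ErrorClass.TRANSPOSITION)
            cls = choices[rng.randrange(len(choices))]
            ch = planned[i].value
            if cls is ErrorClass.REPETITION:
                plan_s, real_s, step = ch, ch + ch, 1
            elif cls is ErrorClass.OMISSION:
                plan_s, real_s, step = ch, "", 1
            elif cls is ErrorClass.TRANSPOSITION:
                nxt = planned[i + 1].value
                plan_s, real_s, step = ch + nxt, nxt + ch, 2
            elif cls is ErrorClass.SUBSTITUTION:
                wrong = ch
                while wrong == ch:
                    wrong = ALPHA[rng.randrange(len(ALPHA))]
                plan_s, real_s, step = ch, wrong, 1
            else:
                extra = ALPHA[rng.randrange(len(ALPHA))]
                plan_s, real_s, step = ch, ch + extra, 1
            events.append(_ev(cls, i, plan_s, real_s, rng.random() < 0.5))
            i += step
        expected_final, expected_harm = oracle_expectation(
            design, intended, events
        )
        out.append(
            Scenario(
                f"random-{idx:04d}", design, intended, tuple(events),
                expected_final, expected_harm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plain-text export


def export_scenarios(scenarios: Sequence[Scenario], directory) -> None:
    """Write a CSV expectation table plus plain-text key logs.

    The pair documents each design's behaviour on concrete keystroke
    sequences and doubles as an audit trail: the key log records what the
    operator actually pressed, not what the design displayed.
    """
    import pandas as pd
    from pathlib import Path

    from .keys import format_keys

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    logs = []
    for sc in scenarios:
        trial = replay_scenario(sc)
        rows.append(
            {
                "name": sc.name,
                "design": sc.design,
                "intended": sc.intended.canonical,
                "expected_final": str(sc.expected_final),
                "expected_harm": sc.expected_harm,
                "n_events": len(sc.scripted_events),
                "attempts": trial.attempts,
            }
        )
        logs.append(f"{sc.name}\t{sc.design}\t{format_keys(trial.realized_keys)}")
    pd.DataFrame(rows).to_csv(directory / "scenarios.csv", index=False)
    (directory / "key_logs.txt").write_text("\n".join(logs) + "\n")
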