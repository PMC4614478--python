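"""The simulated operator: typing errors, noticing, repairs, re-entry.

The operator plans the keystrokes of the intended number and types them
one by one.  At each planned keystroke one of five classic typing-error
classes may fire — repetition, omission, transposition of two adjacent
keys, substitution, insertion — independently and with equal probability
per keystroke.  A fired error is *noticed* immediately with probability
``1 - v``, where ``v`` is the operator's vulnerability (the probability
of not attempting a repair).  A noticed error is repaired with the
canonical repair keystrokes (delete/retype), issued through the design
under test, and the operator then continues as if the repair succeeded:
noticing is per-error, immediate and permanent, and repair keystrokes are
themselves error-free.  Whether a repair actually restores the intended
buffer depends entirely on the design's delete/point semantics — that
dependence is what the simulation measures.

Design N has no delete key: a noticed error is repaired by pressing CLEAR
and retyping the whole number, which terminates the attempt correctly (and
incidentally erases any earlier unnoticed error), so at most one noticed
error can occur per number on design N.

On a submission rejection, designs C/D/E/G/N start a fresh error-prone
attempt; design F — the optimistic lower bound for E — retypes flawlessly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import Decimal
from enum import IntEnum
from typing import Optional, Sequence, Union

from .codec import TargetNumber, value_of, _Invalid
from .designs import check_design, presser_for, _submit_stored
from .keys import (
    ALPHABET_CHARS,
    CLEAR_CHAR,
    DELETE_CHAR,
    Key,
    key_for,
)


class ErrorClass(IntEnum):
    REPETITION = 0
    OMISSION = 1
    TRANSPOSITION = 2
    SUBSTITUTION = 3
    INSERTION = 4


@dataclass(frozen=True)
class ErrorEvent:
    """One injected typing error.

    ``position`` indexes the planned sequence; ``planned_tokens`` are the
    affected planned key(s) and ``realized_tokens`` what was actually
    typed in their place (before any repair).
    """

    error_class: ErrorClass
    position: int
    planned_tokens: tuple[Key, ...]
    realized_tokens: tuple[Key, ...]
    noticed: bool

    def __post_init__(self):
        if self.error_class is ErrorClass.SUBSTITUTION:
            if self.realized_tokens == self.planned_tokens:
                raise ValueError("a substitution must realize a different key")
        if self.error_class is ErrorClass.TRANSPOSITION:
            if len(self.planned_tokens) != 2:
                raise ValueError("a transposition affects two adjacent keys")


@dataclass(frozen=True)
class ErrorModel:
    """Error-process parameters, independent of the operator's vulnerability.

    ``per_class_error_prob`` applies to each of the five classes at every
    planned keystroke (so the total per-keystroke error probability is
    about five times it); ``class_probs`` optionally overrides it with one
    probability per class, in :class:`ErrorClass` order.  Substituted keys
    are drawn uniformly from ``substitution_alphabet`` minus the planned
    key, inserted keys uniformly from ``insertion_alphabet``.
    """

    per_class_error_prob: float = 0.002
    class_probs: Optional[tuple[float, float, float, float, float]] = None
    substitution_alphabet: str = ALPHABET_CHARS
    insertion_alphabet: str = ALPHABET_CHARS
    max_attempts: int = 25

    def probs(self) -> tuple[float, ...]:
        if self.class_probs is not None:
            return tuple(self.class_probs)
        return (self.per_class_error_prob,) * 5

    def __post_init__(self):
        probs = self.probs()
        if len(probs) != 5 or any(p < 0 for p in probs) or sum(probs) > 1:
            raise ValueError("class probabilities must be >= 0 and sum to <= 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if not self.substitution_alphabet or not self.insertion_alphabet:
            raise ValueError("error alphabets must be non-empty")
        bad = set(self.substitution_alphabet + self.insertion_alphabet) - set(
            ALPHABET_CHARS
        )
        if bad:
            raise ValueError(f"error alphabets limited to digits/point, got {bad!r}")


@dataclass(frozen=True)
class OperatorParams(ErrorModel):
    """Error model plus the operator's vulnerability ``v`` in [0, 1]."""

    vulnerability: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.vulnerability <= 1.0:
            raise ValueError("vulnerability must lie in [0, 1]")


class _Compiled:
    """Precomputed sampling constants for the hot loop.

    The five classes are sampled by first hit among independent draws,
    collapsed into a single uniform draw: class ``i`` fires with
    probability ``p_i * prod_{j<i}(1 - p_j)`` and at most one class fires
    per planned keystroke.
    """

    __slots__ = ("cums", "total", "v", "sub_alpha", "ins_alpha", "max_attempts")

    def __init__(self, params: OperatorParams):
        probs = params.probs()
        cums = []
        acc = 0.0
        survive = 1.0
        for p in probs:
            acc += p * survive
            survive *= 1.0 - p
            cums.append(acc)
        self.cums = tuple(cums)
        self.total = cums[-1]
        self.v = params.vulnerability
        self.sub_alpha = params.substitution_alphabet
        self.ins_alpha = params.insertion_alphabet
        self.max_attempts = params.max_attempts


def compile_params(params: OperatorParams) -> _Compiled:
    return _Compiled(params)


# ---------------------------------------------------------------------------
# Repair plans


def repair_plan(
    e: ErrorEvent, design: str = "C", planned: Optional[Sequence[Key]] = None
) -> list[Key]:
    """Canonical repair keystrokes for a noticed error.

    On design N (no delete key) the plan is always CLEAR followed by a
    full flawless retype of the planned sequence.
    """
    if design == "N":
        if planned is None:
            raise ValueError("design N's repair plan needs the planned sequence")
        return [Key.CLEAR, *planned]
    cls = e.error_class
    if cls is ErrorClass.REPETITION or cls is ErrorClass.INSERTION:
        return [Key.DELETE]
    if cls is ErrorClass.OMISSION:
        return [e.planned_tokens[0]]
    if cls is ErrorClass.SUBSTITUTION:
        return [Key.DELETE, e.planned_tokens[0]]
    # transposition: delete two keys, retype them in the correct order
    first, second = e.planned_tokens
    return [Key.DELETE, Key.DELETE, first, second]


def replay_attempt(
    design: str, planned: Sequence[Key], events: Sequence[ErrorEvent]
) -> tuple[str, list[Key]]:
    """Retype a planned sequence with fully scripted errors (no randomness).

    Returns the design's final stored string and the realized key log.
    Each event must be consistent with the planned sequence at its
    position; noticed events trigger the canonical repair (or, on design
    N, clear-and-retype, which ends the attempt).
    """
    check_design(design)
    by_pos = {e.position: e for e in events}
    if len(by_pos) != len(events):
        raise ValueError("at most one scripted event per planned position")
    press = presser_for(design)
    buf: list[str] = []
    realized: list[Key] = []
    i = 0
    n = len(planned)
    while i < n:
        e = by_pos.get(i)
        if e is None:
            press(buf, planned[i].value)
            realized.append(planned[i])
            i += 1
            continue
        step = 2 if e.error_class is ErrorClass.TRANSPOSITION else 1
        if tuple(planned[i : i + step]) != e.planned_tokens:
            raise ValueError(
                f"event at position {i} does not match the planned keys"
            )
        for t in e.realized_tokens:
            press(buf, t.value)
            realized.append(t)
        if e.noticed:
            if design == "N":
                buf.clear()
                realized.append(Key.CLEAR)
                for k in planned:
                    press(buf, k.value)
                    realized.append(k)
                return "".join(buf), realized
            for rk in repair_plan(e):
                press(buf, rk.value)
                realized.append(rk)
        i += step
    return "".join(buf), realized


# ---------------------------------------------------------------------------
# Single error-prone attempt (hot path operates on character strings)


def _pick_other(alpha: str, ch: str, rnd) -> str:
    w = alpha[int(rnd() * len(alpha))]
    while w == ch:
        w = alpha[int(rnd() * len(alpha))]
    return w


def _attempt(press, design: str, planned: str, cp: _Compiled, rng, record: bool):
    """Type the planned characters once through a design, injecting errors.

    Returns ``(buf, events, realized)`` where ``buf`` is the design's
    stored character list; ``events``/``realized`` are populated only when
    ``record`` is true (the bulk Monte Carlo path skips the bookkeeping).
    """
    buf: list[str] = []
    events = [] if record else None
    realized = [] if record else None
    rnd = rng.random
    cums = cp.cums
    total = cp.total
    notice_p = 1.0 - cp.v
    n = len(planned)
    i = 0
    while i < n:
        ch = planned[i]
        u = rnd()
        if u >= total:
            press(buf, ch)
            if record:
                realized.append(ch)
            i += 1
            continue
        if u < cums[0]:
            cls = 0
        elif u < cums[1]:
            cls = 1
        elif u < cums[2]:
            cls = 2
        elif u < cums[3]:
            cls = 3
        else:
            cls = 4
        if cls == 2 and i == n - 1:
            # a transposition needs a successor key; at the last keystroke
            # the draw falls through to error-free typing
            press(buf, ch)
            if record:
                realized.append(ch)
            i += 1
            continue
        # realize the erroneous keystrokes
        if cls == 0:  # repetition
            typed = (ch, ch)
            plan_toks = (ch,)
            repair = (DELETE_CHAR,)
            step = 1
        elif cls == 1:  # omission
            typed = ()
            plan_toks = (ch,)
            repair = (ch,)
            step = 1
        elif cls == 2:  # transposition of two adjacent keys
            nxt = planned[i + 1]
            typed = (nxt, ch)
            plan_toks = (ch, nxt)
            repair = (DELETE_CHAR, DELETE_CHAR, ch, nxt)
            step = 2
        elif cls == 3:  # substitution
            wrong = _pick_other(cp.sub_alpha, ch, rnd)
            typed = (wrong,)
            plan_toks = (ch,)
            repair = (DELETE_CHAR, ch)
            step = 1
        else:  # insertion after the planned key
            extra = cp.ins_alpha[int(rnd() * len(cp.ins_alpha))]
            typed = (ch, extra)
            plan_toks = (ch,)
            repair = (DELETE_CHAR,)
            step = 1
        for t in typed:
            press(buf, t)
        noticed = rnd() < notice_p
        if record:
            realized.extend(typed)
            events.append(
                ErrorEvent(
                    ErrorClass(cls),
                    i,
                    tuple(key_for(t) for t in plan_toks),
                    tuple(key_for(t) for t in typed),
                    noticed,
                )
            )
        if noticed:
            if design == "N":
                # no delete key: clear and retype the whole number flawlessly,
                # which ends the attempt correctly
                buf.clear()
                for c in planned:
                    buf.append(c)
                if record:
                    realized.append(CLEAR_CHAR)
                    realized.extend(planned)
                return buf, events, realized
            for rc in repair:
                press(buf, rc)
            if record:
                realized.extend(repair)
        i += step
    return buf, events, realized


# ---------------------------------------------------------------------------
# Trials


@dataclass(frozen=True)
class EntryTrial:
    """One simulated number entry, possibly spanning several attempts.

    ``harm`` is 1 iff the finally accepted value differs from the intended
    value by exact decimal comparison (an INVALID final reading counts as
    harm).  Trials that hit the attempt cap are flagged via ``capped`` and
    carry ``final_value=None`` — they are counted, never dropped.
    """

    intended: TargetNumber
    design: str
    realized_keys: tuple[Key, ...]
    events: tuple[ErrorEvent, ...]
    final_value: Union[Decimal, _Invalid, None]
    harm: int
    attempts: int
    capped: bool = False

    @property
    def n_errors(self) -> int:
        return len(self.events)

    @property
    def n_noticed(self) -> int:
        return sum(1 for e in self.events if e.noticed)


def _trial_harm_exact(stored: str, target: TargetNumber) -> int:
    if stored == target.canonical:
        return 0
    return 0 if value_of(stored) == target.value else 1


def inject_and_type(
    design: str,
    planned: Sequence[Key],
    params: OperatorParams,
    rng: random.Random,
) -> EntryTrial:
    """Run a single error-prone attempt (no submission checks, no re-entry).

    The trial's final value is the numeric reading of the buffer after the
    last planned keystroke (and any repairs); useful for inspecting how a
    design mangles individual attempts.
    """
    check_design(design)
    if any(k in (Key.DELETE, Key.CLEAR, Key.ENTER) for k in planned):
        raise ValueError("planned keystrokes contain only digits and the point")
    planned_chars = "".join(k.value for k in planned)
    target = TargetNumber.from_string(planned_chars)
    cp = _Compiled(params)
    buf, events, realized = _attempt(
        presser_for(design), design, planned_chars, cp, rng, record=True
    )
    stored = "".join(buf)
    val = value_of(stored)
    return EntryTrial(
        intended=target,
        design=design,
        realized_keys=tuple(key_for(c) for c in realized),
        events=tuple(events),
        final_value=val,
        harm=0 if val == target.value else 1,
        attempts=1,
    )


def _run_trial(press, design: str, target_canonical: str, target, cp: _Compiled, rng):
    """Fast complete trial: returns ``(accepted_stored | None, attempts)``.

    ``None`` means the attempt cap was reached without an acceptance.
    """
    last_sub = None
    for attempt in range(1, cp.max_attempts + 1):
        if design == "F" and attempt > 1:
            # optimistic bound: the re-entry after an ISMP rejection is flawless
            stored = target_canonical
        else:
            buf, _, _ = _attempt(press, design, target_canonical, cp, rng, False)
            stored = "".join(buf)
        accepted, _, last_sub = _submit_stored(design, stored, target, last_sub)
        if accepted:
            return stored, attempt
    return None, cp.max_attempts


def simulate_entry(
    design: str,
    target: TargetNumber,
    params: OperatorParams,
    rng: random.Random,
    record: bool = False,
) -> EntryTrial:
    """Run one complete number entry, including design-driven re-entries."""
    check_design(design)
    cp = _Compiled(params)
    press = presser_for(design)
    if not record:
        stored, attempts = _run_trial(press, design, target.canonical, target, cp, rng)
        if stored is None:
            return EntryTrial(target, design, (), (), None, 1, attempts, capped=True)
        return EntryTrial(
            target, design, (), (), value_of(stored),
            _trial_harm_exact(stored, target), attempts,
        )
    # full-fidelity path: keep the key log and error events across attempts
    all_keys: list[Key] = []
    all_events: list[ErrorEvent] = []
    last_sub = None
    canonical = target.canonical
    for attempt in range(1, cp.max_attempts + 1):
        if attempt > 1:
            all_keys.append(Key.CLEAR)  # a rejection clears the display
        if design == "F" and attempt > 1:
            stored = canonical
            all_keys.extend(key_for(c) for c in canonical)
        else:
            buf, events, realized = _attempt(press, design, canonical, cp, rng, True)
            stored = "".join(buf)
            all_keys.extend(key_for(c) for c in realized)
            all_events.extend(events)
        all_keys.append(Key.ENTER)
        accepted, _, last_sub = _submit_stored(design, stored, target, last_sub)
        if accepted:
            val = value_of(stored)
            return EntryTrial(
                target, design, tuple(all_keys), tuple(all_events), val,
                0 if val == target.value else 1, attempt,
            )
    return EntryTrial(
        target, design, tuple(all_keys), tuple(all_events), None, 1,
        cp.max_attempts, capped=True,
    )
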