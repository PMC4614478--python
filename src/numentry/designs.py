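"""Executable state machines for the eight number-entry designs.

Four common commercial designs (A, B, C, N) and four proposals (D, E, F,
G) share one key-processing interface plus a submission-time accept/reject
rule.  All designs accept digit keys by appending them and empty the
buffer on CLEAR; they differ in how DELETE and the decimal point behave
and in what they check at submission:

=======  ==========================  =====================================
design   keystroke handling          submission rule
=======  ==========================  =====================================
A        DELETE removes the          always accepts
         rightmost *digit*, never a
         point; a second point is
         silently ignored
B        DELETE removes the          always accepts
         rightmost token; a second
         point is silently ignored
C        digits and points treated   rejects syntactically invalid input
         equally; DELETE removes     (two or more stored points)
         the rightmost token
D        as C                        as C, plus blocks any entry with
                                     adjacent identical tokens until the
                                     same token string is submitted twice
                                     in a row (key-bounce interception)
E        as C                        as C, plus rejects entries failing
                                     the ISMP dose-notation rules
F        as C                        as E (the re-entry after a rejection
                                     is modelled as flawless: an optimistic
                                     lower bound for design E)
G        as C                        as C, plus rejects values not within
                                     a factor of 5 of the intended value
                                     (a dose-error-reduction hard limit)
N        no DELETE key; noticed      as C (invalid syntax is rejected and
         errors are repaired by      the number re-entered)
         CLEAR and full re-entry
=======  ==========================  =====================================

Designs A and B can never hold two points, so their stored string is
always a valid numeral.  Design N has no delete key, so its buffer never
shrinks except via CLEAR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from .codec import TargetNumber, ismp_valid, value_of, _Invalid
from .keys import CLEAR_CHAR, DELETE_CHAR, Key

DESIGN_IDS = ("A", "B", "C", "D", "E", "F", "G", "N")

SHORT_NAMES = {
    "A": "Broken delete & decimals",
    "B": "Fixed delete only",
    "C": "Fixed delete & decimals",
    "D": "Debounced",
    "E": "ISMP",
    "F": "Low bound ISMP",
    "G": "Range check",
    "N": "No delete (clear only)",
}


def check_design(design: str) -> str:
    if design not in DESIGN_IDS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGN_IDS}")
    return design


# ---------------------------------------------------------------------------
# Keystroke processing (internal fast path: a mutable list of characters)


def _press_normal(buf: list, ch: str) -> None:  # designs C, D, E, F, G
    if ch != DELETE_CHAR and ch != CLEAR_CHAR:
        buf.append(ch)
    elif ch == DELETE_CHAR:
        if buf:
            buf.pop()
    else:
        buf.clear()


def _press_A(buf: list, ch: str) -> None:
    # delete removes the rightmost digit and never a point; second point ignored
    if ch == DELETE_CHAR:
        for i in range(len(buf) - 1, -1, -1):
            if buf[i] != ".":
                del buf[i]
                break
    elif ch == ".":
        if "." not in buf:
            buf.append(ch)
    elif ch == CLEAR_CHAR:
        buf.clear()
    else:
        buf.append(ch)


def _press_B(buf: list, ch: str) -> None:
    # delete removes the rightmost token; second point ignored
    if ch == DELETE_CHAR:
        if buf:
            buf.pop()
    elif ch == ".":
        if "." not in buf:
            buf.append(ch)
    elif ch == CLEAR_CHAR:
        buf.clear()
    else:
        buf.append(ch)


def _press_N(buf: list, ch: str) -> None:
    # no delete key
    if ch == DELETE_CHAR:
        return
    if ch == CLEAR_CHAR:
        buf.clear()
    else:
        buf.append(ch)


_PRESSERS = {
    "A": _press_A,
    "B": _press_B,
    "C": _press_normal,
    "D": _press_normal,
    "E": _press_normal,
    "F": _press_normal,
    "G": _press_normal,
    "N": _press_N,
}


def presser_for(design: str):
    """The keystroke-processing function of one design (internal fast path)."""
    return _PRESSERS[check_design(design)]


# ---------------------------------------------------------------------------
# Public buffer interface


@dataclass(frozen=True)
class EntryBuffer:
    """A design's internal display state.

    ``stored`` is the ordered token string as the design stored it;
    ``last_submission`` is the previously *submitted* token string, used
    only by design D's double-entry confirmation.
    """

    stored: str = ""
    last_submission: Optional[str] = None

    @property
    def point_registered(self) -> bool:
        """Whether a decimal point is currently registered (designs A/B)."""
        return "." in self.stored


def apply_key(design: str, buffer: EntryBuffer, key: Key) -> EntryBuffer:
    """Process one keystroke under a design; total on the whole alphabet.

    ENTER is handled by :func:`submit`, not here.
    """
    if key is Key.ENTER:
        raise ValueError("ENTER is handled by submit(), not apply_key()")
    buf = list(buffer.stored)
    _PRESSERS[check_design(design)](buf, key.value)
    return replace(buffer, stored="".join(buf))


def apply_keys(design: str, buffer: EntryBuffer, keys: Sequence[Key]) -> EntryBuffer:
    buf = list(buffer.stored)
    press = _PRESSERS[check_design(design)]
    for k in keys:
        if k is Key.ENTER:
            raise ValueError("ENTER is handled by submit(), not apply_keys()")
        press(buf, k.value)
    return replace(buffer, stored="".join(buf))


# ---------------------------------------------------------------------------
# Submission


@dataclass(frozen=True)
class SubmitResult:
    """Outcome of pressing ENTER: accept with a value, or reject with a reason.

    ``buffer`` is the post-submission buffer state (design D records a
    rejected repeat-containing entry into ``last_submission``).
    """

    accepted: bool
    value: Union[Decimal, _Invalid, None]
    reason: Optional[str]
    buffer: EntryBuffer


def _has_adjacent_repeat(s: str) -> bool:
    return any(s[i] == s[i + 1] for i in range(len(s) - 1))


def _submit_stored(
    design: str, stored: str, target: TargetNumber, last_sub: Optional[str]
) -> tuple[bool, Optional[str], Optional[str]]:
    """Internal accept/reject rule on a stored string.

    Returns ``(accepted, reason, new_last_submission)``.  ``target`` is the
    trial's intended number; only design G's range check consults it
    (modelling a dose-error-reduction hard limit configured to the
    prescribed dose).
    """
    if design == "A" or design == "B":
        return True, None, last_sub
    if stored.count(".") >= 2:
        return False, "invalid-syntax", last_sub
    if design == "D":
        if stored != last_sub and _has_adjacent_repeat(stored):
            return False, "repeat-unconfirmed", stored
        return True, None, last_sub
    if design == "E" or design == "F":
        if not ismp_valid(stored):
            return False, "ismp", last_sub
        return True, None, last_sub
    if design == "G":
        if stored != target.canonical:
            v = value_of(stored)
            n = target.value
            if (v == 0) != (n == 0):
                return False, "range", last_sub
            if v != 0:
                lo, hi = (v, n) if v < n else (n, v)
                if hi >= 5 * lo:
                    return False, "range", last_sub
        return True, None, last_sub
    # C and N accept anything syntactically valid
    return True, None, last_sub


def submit(design: str, buffer: EntryBuffer, intended: TargetNumber) -> SubmitResult:
    """Press ENTER: the design accepts the entered value or rejects it."""
    check_design(design)
    accepted, reason, last_sub = _submit_stored(
        design, buffer.stored, intended, buffer.last_submission
    )
    out = replace(buffer, last_submission=last_sub)
    value = value_of(buffer.stored) if accepted else None
    return SubmitResult(accepted, value, reason, out)


# ---------------------------------------------------------------------------
# Independent oracle


def reference_interpreter(design: str, keys: Sequence[Key]) -> str:
    """Deliberately naive re-implementation of the keystroke semantics.

    Coded separately from :func:`apply_key` (plain string editing instead
    of the list-based fast path) to serve as a differential-testing oracle;
    the two must agree on every key sequence.
    """
    check_design(design)
    s = ""
    for k in keys:
        c = k.value if isinstance(k, Key) else k
        if c == CLEAR_CHAR:
            s = ""
        elif c == DELETE_CHAR:
            if design == "N":
                pass
            elif design == "A":
                last_digit = max(s.rfind(d) for d in "0123456789")
                if last_digit >= 0:
                    s = s[:last_digit] + s[last_digit + 1 :]
            else:
                s = s[:-1]
        elif c == ".":
            if design in ("A", "B"):
                if "." not in s:
                    s = s + "."
            else:
                s = s + "."
        elif c in "0123456789":
            s = s + c
        else:
            raise ValueError(f"not an entry key: {k!r}")
    return s


# ---------------------------------------------------------------------------
# Machine-readable design summary


def design_table() -> pd.DataFrame:
    """Design properties as a table (exportable to CSV for documentation)."""
    rows = []
    delete_sem = {
        "A": "removes rightmost digit, never a point",
        "N": "no delete key",
    }
    point_policy = {
        "A": "second point silently ignored",
        "B": "second point silently ignored",
    }
    submit_checks = {
        "A": "none",
        "B": "none",
        "C": "syntax",
        "D": "syntax; adjacent repeats need double entry",
        "E": "syntax; ISMP notation",
        "F": "syntax; ISMP notation (flawless re-entry bound)",
        "G": "syntax; value within factor 5 of intended",
        "N": "syntax",
    }
    for d in DESIGN_IDS:
        rows.append(
            {
                "design": d,
                "short_name": SHORT_NAMES[d],
                "delete_semantics": delete_sem.get(d, "removes rightmost token"),
                "point_policy": point_policy.get(d, "all points stored"),
                "submit_checks": submit_checks[d],
            }
        )
    return pd.DataFrame(rows)
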