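"""Target numbers, keystroke encoding, buffer valuation and ISMP syntax.

Dose-like target values are exact decimal quantities.  All value
comparisons in the simulator are *decimal* comparisons (``"2.50"`` and
``"2.5"`` are equal in value), so the harm indicator — entered value
differs from intended value — is unambiguous.  A lone decimal point or an
empty buffer evaluates to 0, which is how common devices display it; a
buffer holding two or more points has no numeric reading and evaluates to
the :data:`INVALID` sentinel.

The ISMP (Institute for Safe Medication Practices) dose-notation rules
implemented here: a number must be non-empty, contain at most one decimal
point with at least one digit on each side of it, carry a leading zero
(``0.5``, never ``.5``), no superfluous leading zeros (``05`` is invalid)
and no trailing zeros in the fractional part (``5``, never ``5.0``).
Every numeric value has exactly one ISMP-valid rendering, its canonical
string, so ISMP checking constrains *syntax* without constraining values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Union

from .keys import DIGIT_CHARS, Key, key_for


class _Invalid:
    """Sentinel for a buffer with no numeric reading (two or more points)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "INVALID"


INVALID = _Invalid()


class TargetNumber:
    """An exact non-negative decimal target with its canonical rendering.

    The canonical string has no superfluous leading zeros (a single ``0``
    before the point is required), no trailing fractional zeros, and parses
    back to the value exactly.
    """

    __slots__ = ("canonical", "_value")

    def __init__(self, canonical: str):
        if not _is_canonical(canonical):
            raise ValueError(f"not a canonical decimal string: {canonical!r}")
        self.canonical = canonical
        self._value: Decimal | None = None

    @property
    def value(self) -> Decimal:
        if self._value is None:
            self._value = Decimal(self.canonical)
        return self._value

    @classmethod
    def from_string(cls, text: str) -> "TargetNumber":
        """Build a target from any digits/point rendering, canonicalizing it.

        ``"2.50"`` and ``"02.5"`` both yield the target ``2.5``.
        """
        text = text.strip()
        if not text or text.count(".") > 1 or text.strip("0123456789.") != "" :
            raise ValueError(f"not a non-negative decimal numeral: {text!r}")
        if not any(c in DIGIT_CHARS for c in text):
            raise ValueError(f"no digits in numeral: {text!r}")
        return cls(canonical_string(Decimal(text)))

    @classmethod
    def from_value(cls, value: Union[int, str, Decimal]) -> "TargetNumber":
        dec = Decimal(value)
        if dec < 0:
            raise ValueError("targets are non-negative")
        return cls(canonical_string(dec))

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetNumber) and other.canonical == self.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __repr__(self) -> str:
        return f"TargetNumber({self.canonical})"


def _is_canonical(s: str) -> bool:
    if not s or s.strip("0123456789.") != "" or s.count(".") > 1:
        return False
    ipart, dot, fpart = s.partition(".")
    if not ipart:
        return False
    if len(ipart) > 1 and ipart[0] == "0":
        return False
    if dot and (not fpart or fpart[-1] == "0"):
        return False
    return True


def canonical_string(value: Decimal) -> str:
    """Render an exact decimal value canonically (no exponent notation)."""
    s = format(value, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    if not s:
        s = "0"
    if s.startswith("."):
        s = "0" + s
    return s


# ---------------------------------------------------------------------------
# Target generation


def _render_scaled(significand: int, exponent: int) -> str:
    """Canonical rendering of ``significand * 10**exponent`` by string shift."""
    digits = str(significand)
    if exponent >= 0:
        return digits + "0" * exponent
    shift = -exponent
    if shift < len(digits):
        ipart, fpart = digits[:-shift], digits[-shift:]
    else:
        ipart, fpart = "0", "0" * (shift - len(digits)) + digits
    fpart = fpart.rstrip("0")
    return f"{ipart}.{fpart}" if fpart else ipart


@dataclass(frozen=True)
class TargetDistribution:
    """Drug-dose-like target distribution.

    A significand with between ``sig_digits[0]`` and ``sig_digits[1]``
    digits is drawn uniformly (digit count first, then uniformly among the
    integers of that length), then scaled by ``10**e`` with ``e`` uniform on
    ``exponents`` (inclusive).  Defaults give values such as 7, 0.25, 125,
    50 000 — the magnitudes and precisions of typical medication doses.
    ``significand_range`` overrides the digit-count draw with a uniform
    integer draw on an explicit inclusive range.
    """

    sig_digits: tuple[int, int] = (1, 3)
    exponents: tuple[int, int] = (-2, 3)
    significand_range: tuple[int, int] | None = None

    def __post_init__(self):
        lo, hi = self.sig_digits
        if not (1 <= lo <= hi):
            raise ValueError("sig_digits bounds must satisfy 1 <= lo <= hi")
        if self.exponents[0] > self.exponents[1]:
            raise ValueError("exponent bounds out of order")
        if self.significand_range is not None:
            slo, shi = self.significand_range
            if not (1 <= slo <= shi):
                raise ValueError("significand_range must satisfy 1 <= lo <= hi")

    def draw_canonical(self, rng: random.Random) -> str:
        if self.significand_range is not None:
            s = rng.randint(*self.significand_range)
        else:
            ndig = rng.randint(*self.sig_digits)
            s = rng.randint(10 ** (ndig - 1), 10**ndig - 1)
        e = rng.randint(*self.exponents)
        return _render_scaled(s, e)

    def draw(self, rng: random.Random) -> TargetNumber:
        return TargetNumber(self.draw_canonical(rng))


@dataclass(frozen=True)
class FixedTargets:
    """Deterministic replay source: draws uniformly from an explicit list."""

    targets: tuple[TargetNumber, ...]

    def __post_init__(self):
        if not self.targets:
            raise ValueError("target list is empty")

    @classmethod
    def of(cls, *values) -> "FixedTargets":
        return cls(tuple(TargetNumber.from_value(v) for v in values))

    def draw_canonical(self, rng: random.Random) -> str:
        ts = self.targets
        return (ts[0] if len(ts) == 1 else ts[rng.randrange(len(ts))]).canonical

    def draw(self, rng: random.Random) -> TargetNumber:
        return TargetNumber(self.draw_canonical(rng))


TargetSource = Union[TargetDistribution, FixedTargets]


def generate_target(dist: TargetSource, rng: random.Random) -> TargetNumber:
    """Draw one target number; reproducible given the RNG state."""
    return dist.draw(rng)


# ---------------------------------------------------------------------------
# Encoding and valuation


def encode_number(n: TargetNumber) -> list[Key]:
    """Convert a target to the keystrokes of its canonical rendering.

    The planned sequence contains digits and at most one POINT — never
    DELETE, CLEAR or ENTER.
    """
    return [key_for(c) for c in n.canonical]


def value_of(stored: str) -> Union[Decimal, _Invalid]:
    """Numeric valuation of a design's stored digit/point string.

    Zero digits (empty buffer or a lone point) read as 0; two or more
    stored points have no reading and yield :data:`INVALID`.
    """
    if stored.count(".") >= 2:
        return INVALID
    if not stored or stored == ".":
        return Decimal(0)
    return Decimal(stored)


# ---------------------------------------------------------------------------
# ISMP syntax


@dataclass(frozen=True)
class IsmpRuleSet:
    """Switchable ISMP dose-notation rules (all enabled by default).

    ``require_leading_zero`` governs the integer part: at least one digit
    before any point and no superfluous leading zeros.
    ``forbid_trailing_fraction_zeros`` governs the fractional part: if a
    point is present there must be at least one digit after it and the last
    fractional digit must not be zero.
    """

    require_leading_zero: bool = True
    forbid_trailing_fraction_zeros: bool = True
    forbid_multiple_points: bool = True
    forbid_empty: bool = True


DEFAULT_ISMP_RULES = IsmpRuleSet()


def ismp_valid(s: str, rules: IsmpRuleSet = DEFAULT_ISMP_RULES) -> bool:
    """Check a digit/point string against the ISMP notation rules."""
    if s.strip("0123456789.") != "":
        raise ValueError(f"not a digit/point string: {s!r}")
    if not s:
        return not rules.forbid_empty
    if rules.forbid_multiple_points and s.count(".") > 1:
        return False
    ipart, dot, fpart = s.partition(".")
    if rules.require_leading_zero:
        if not ipart:
            return False
        if len(ipart) > 1 and ipart[0] == "0":
            return False
    if rules.forbid_trailing_fraction_zeros and dot:
        if not fpart or fpart[-1] == "0":
            return False
    return True


def ismp_normalize(n: TargetNumber) -> str:
    """The unique ISMP-valid rendering of a target: its canonical string."""
    return n.canonical


# ---------------------------------------------------------------------------
# Plain-text target lists


def read_targets(path: Union[str, Path]) -> FixedTargets:
    """Read a one-number-per-line target list (blank lines, # comments ok)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(TargetNumber.from_string(line))
    return FixedTargets(tuple(out))


def write_targets(path: Union[str, Path], targets: Iterable[TargetNumber]) -> None:
    Path(path).write_text("".join(t.canonical + "\n" for t in targets))
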