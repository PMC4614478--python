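"""Key alphabet for number-entry interfaces.

The entry alphabet is closed: ten digit keys, the decimal point, DELETE,
CLEAR and ENTER.  Internally keys are represented by single printable
characters so that key logs can be stored and diffed as plain text:

====== =========
key    character
====== =========
D0..D9 ``0``..``9``
POINT  ``.``
DELETE ``<``
CLEAR  ``#``
ENTER  ``=``
====== =========
"""

from __future__ import annotations

from enum import Enum


class Key(Enum):
    """One token of the entry alphabet."""

    D0 = "0"
    D1 = "1"
    D2 = "2"
    D3 = "3"
    D4 = "4"
    D5 = "5"
    D6 = "6"
    D7 = "7"
    D8 = "8"
    D9 = "9"
    POINT = "."
    DELETE = "<"
    CLEAR = "#"
    ENTER = "="

    @property
    def char(self) -> str:
        return self.value

    @property
    def is_digit(self) -> bool:
        return self.value.isdigit()

    def __repr__(self) -> str:  # compact logs: Key.D1 -> D1
        return self.name


DIGIT_CHARS = "0123456789"
#: characters a design can store in its entry buffer
STORABLE_CHARS = DIGIT_CHARS + "."
#: characters an erroneous keystroke can produce (no control keys)
ALPHABET_CHARS = STORABLE_CHARS

DELETE_CHAR = Key.DELETE.value
CLEAR_CHAR = Key.CLEAR.value
ENTER_CHAR = Key.ENTER.value

_CHAR_TO_KEY = {k.value: k for k in Key}


def key_for(char: str) -> Key:
    """Map a single character to its :class:`Key`."""
    try:
        return _CHAR_TO_KEY[char]
    except KeyError:
        raise ValueError(f"not a key character: {char!r}") from None


def parse_keys(text: str) -> list[Key]:
    """Parse a key-log string (e.g. ``"1..5<"``) into keys.

    Whitespace is ignored so logs may be space-separated for readability.
    """
    return [key_for(c) for c in text if not c.isspace()]


def format_keys(keys: list[Key] | tuple[Key, ...]) -> str:
    """Render keys as a compact key-log string."""
    return "".join(k.value for k in keys)
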