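"""Rendering and parsing of the French date phrases found in reports.

Two surface styles are supported, matching what the corpus generator
emits: ``24 mai 2022`` (long form, possibly with accented month names)
and ``24/05/2022`` (numeric form).  Parsing operates on *normalized*
text (lowercased, accents stripped).
"""

from __future__ import annotations

import re
from datetime import date as Date

#: accented display forms, indexed by month - 1.
MONTHS_DISPLAY = [
    "janvier", "février", "mars", "avril", "mai", "juin",
    "juillet", "août", "septembre", "octobre", "novembre", "décembre",
]

#: normalized (accent-stripped) forms, as seen after text normalization.
MONTHS_NORM = [
    "janvier", "fevrier", "mars", "avril", "mai", "juin",
    "juillet", "aout", "septembre", "octobre", "novembre", "decembre",
]
_MONTH_INDEX = {m: i + 1 for i, m in enumerate(MONTHS_NORM)}

#: matches either style on normalized text.
DATE_PHRASE_RE = re.compile(
    r"\b(?:"
    r"(?P<d1>\d{1,2})/(?P<m1>\d{1,2})/(?P<y1>\d{4})"
    r"|"
    r"(?P<d2>\d{1,2})(?:er)? (?P<m2>" + "|".join(MONTHS_NORM) + r") (?P<y2>\d{4})"
    r")\b"
)


def format_date_fr(d: Date, style: str = "long") -> str:
    """Render a date as report text; ``style`` is ``"long"`` or ``"numeric"``."""
    if style == "numeric":
        return f"{d.day:02d}/{d.month:02d}/{d.year}"
    return f"{d.day} {MONTHS_DISPLAY[d.month - 1]} {d.year}"


def parse_date_match(m: re.Match) -> Date | None:
    """Parse a :data:`DATE_PHRASE_RE` match; None if the date is invalid."""
    try:
        if m.group("d1"):
            return Date(int(m.group("y1")), int(m.group("m1")), int(m.group("d1")))
        return Date(int(m.group("y2")), _MONTH_INDEX[m.group("m2")], int(m.group("d2")))
    except ValueError:
        return None
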