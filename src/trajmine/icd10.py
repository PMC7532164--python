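"""ICD-10 level-3 code handling: truncation and chapter classification.

A level-3 code is one letter followed by two digits (``I10``, ``Q90``).
Registries in the wild carry sub-level digits (``Q90.1``) or national
prefixes (the Danish dialect writes ``DI109`` for I10.9); both are
reduced to the three-character core before any analysis.

The artificial code ``Y99`` marks death within the mortality horizon of a
preceding diagnosis.  Its letter falls inside chapter XX (external causes
of morbidity and mortality), which is normally excluded, so it is carried
on an explicit allow-list wherever chapters are filtered.
"""

from __future__ import annotations

import re

#: Artificial terminal code linking the patient register to the death register.
DEATH_CODE = "Y99"

_LEVEL3 = re.compile(r"^[A-Z][0-9]{2}$")
_CORE = re.compile(r"^([A-Z])([0-9]{2})")

# Chapter ranges of the WHO ICD-10 index, closed intervals of level-3 codes.
# Fixed-width letter+digit codes compare correctly as plain strings.
CHAPTER_RANGES: tuple[tuple[str, str, str], ...] = (
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
    ("XV", "O00", "O99"),
    ("XVI", "P00", "P96"),
    ("XVII", "Q00", "Q99"),
    ("XVIII", "R00", "R99"),
    ("XIX", "S00", "T98"),
    ("XX", "V01", "Y98"),
    ("XXI", "Z00", "Z99"),
    ("XXII", "U00", "U85"),
)

#: All recognised chapter labels.
KNOWN_CHAPTERS = frozenset(label for label, _, _ in CHAPTER_RANGES)

#: Chapters excluded from trajectory mining by default: perinatal conditions
#: (XVI), symptoms and findings (XVIII), injury (XIX), external causes (XX)
#: and contact-with-health-services factors (XXI).
DEFAULT_EXCLUDED_CHAPTERS = frozenset({"XVI", "XVIII", "XIX", "XX", "XXI"})


class CodeError(ValueError):
    """A diagnosis code could not be interpreted."""


def truncate_to_level3(raw_code: str) -> str:
    """Reduce a raw diagnosis code to its ICD-10 level-3 form.

    Strips surrounding whitespace, upper-cases, removes a single-letter
    national prefix when the string starts with two letters, then keeps
    the leading letter + two digits and drops any sub-level suffix.
    Idempotent on codes that are already level 3.

    Raises
    ------
    CodeError
        If no letter + two-digit core can be extracted.
    """
    if not isinstance(raw_code, str) or not raw_code.strip():
        raise CodeError(f"empty or non-string diagnosis code: {raw_code!r}")
    code = raw_code.strip().upper()
    if len(code) >= 2 and code[0].isalpha() and code[1].isalpha():
        code = code[1:]  # Danish-style national prefix, e.g. "DI109"
    m = _CORE.match(code)
    if m is None:
        raise CodeError(f"cannot extract a level-3 core from {raw_code!r}")
    return m.group(0)


def is_level3(code: str) -> bool:
    """True when *code* is exactly one letter followed by two digits."""
    return bool(_LEVEL3.match(code))


def chapter_of(code: str) -> str:
    """Roman-numeral ICD-10 chapter label of a level-3 *code*.

    The death code Y99 sits just past the chapter-XX range (which ends at
    Y98 -- the reason it was free to repurpose) and is reported as "XX".
    """
    if code == DEATH_CODE:
        return "XX"
    if not is_level3(code):
        raise CodeError(f"not a level-3 code: {code!r}")
    for label, lo, hi in CHAPTER_RANGES:
        if lo <= code <= hi:
            return label
    raise CodeError(f"code {code!r} falls outside every ICD-10 chapter range")
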