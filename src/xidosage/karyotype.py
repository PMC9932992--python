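"""Karyotype string parsing and formatting.

Clinical karyotype strings such as ``"45,X"``, ``"47,XXY"`` or ``"47,XX,+21"``
encode the total chromosome count, the sex-chromosome complement, and an
optional trisomy-21 suffix.  The parser is strict: the leading total must be
consistent with the listed sex chromosomes (44 autosomes + X's + Y's + one
extra for a ``+21``), at least one X must be present, and anything else is
rejected with the offending token.
"""

from __future__ import annotations

import re

__all__ = ["parse_karyotype", "format_karyotype"]

_KARYO_RE = re.compile(
    r"^\s*(?P<total>\d+)\s*,\s*(?P<sex>[XYxy]+)\s*(?P<t21>,\s*\+\s*21\s*)?$"
)


def parse_karyotype(karyotype: str) -> tuple[int, int, int]:
    """Parse a karyotype string into (x_count, y_count, chr21_count).

    Accepts optional spaces after commas and case-insensitive sex-chromosome
    letters.  ``chr21_count`` is 3 when a ``+21`` suffix is present, else 2.

    Raises
    ------
    ValueError
        If the string is malformed, contains zero X chromosomes, or the
        leading total disagrees with the listed chromosomes.
    """
    if not isinstance(karyotype, str):
        raise ValueError(f"karyotype must be a string, got {karyotype!r}")
    m = _KARYO_RE.match(karyotype)
    if m is None:
        raise ValueError(f"malformed karyotype string: {karyotype!r}")
    sex = m.group("sex").upper()
    x_count = sex.count("X")
    y_count = sex.count("Y")
    if x_count + y_count != len(sex):  # pragma: no cover - regex guarantees
        raise ValueError(f"unexpected sex-chromosome letters in {karyotype!r}")
    if x_count == 0:
        raise ValueError(
            f"karyotype {karyotype!r} has zero X chromosomes (token {sex!r})"
        )
    chr21_count = 3 if m.group("t21") else 2
    total = int(m.group("total"))
    expected = 44 + x_count + y_count + (chr21_count - 2)
    if total != expected:
        raise ValueError(
            f"karyotype {karyotype!r}: leading total {total} inconsistent with "
            f"sex chromosomes {sex!r} (expected {expected})"
        )
    return x_count, y_count, chr21_count


def format_karyotype(x_count: int, y_count: int, chr21_count: int = 2) -> str:
    """Format copy numbers as a karyotype string; inverse of parse_karyotype."""
    if x_count < 1:
        raise ValueError("x_count must be >= 1")
    if y_count < 0:
        raise ValueError("y_count must be >= 0")
    if chr21_count not in (2, 3):
        raise ValueError("chr21_count must be 2 or 3")
    total = 44 + x_count + y_count + (chr21_count - 2)
    s = f"{total},{'X' * x_count}{'Y' * y_count}"
    if chr21_count == 3:
        s += ",+21"
    return s
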