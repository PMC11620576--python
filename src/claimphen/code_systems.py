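"""Drug- and diagnosis-code systems used in Japanese medical billing data.

Two code systems appear in the billing records this package analyses:

* **MHLW drug codes** — 12-character codes issued by Japan's Ministry of
  Health, Labour and Welfare.  The code carries a hierarchy: a 4-digit
  therapeutic class (whose first 3 digits are an upper class), a 3-digit
  compound number that also encodes the administration route, a form
  letter, a dose-unit digit, and a 3-digit product number.  For example
  ``2171005F2021`` is an oral tablet of dilazep hydrochloride hydrate:
  class 2171 (coronary vasodilators, upper class 217), compound 005
  (oral range), form F (tablet), dose unit 2, product 021.

* **ICD-10 diagnosis codes** — e.g. ``N028`` (IgA nephropathy).

This module parses MHLW codes, maps codes onto the grouping keys used by
the feature-compilation schemes (drug class + route; truncated ICD-10),
and matches the wildcard code patterns used by the rule-based criteria.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

__all__ = [
    "Route",
    "MHLWDrugCode",
    "CodeGroupKey",
    "MalformedCodeError",
    "NEPHROLOGY_EXCLUDED",
    "parse_mhlw_code",
    "drug_group_key",
    "icd10_group_key",
    "matches_code_pattern",
]


class MalformedCodeError(ValueError):
    """A code does not conform to its system's grammar."""


class Route(str, enum.Enum):
    """Administration route, encoded in the MHLW compound-number range."""

    ORAL = "oral"          # compound 000-399
    INFUSION = "infusion"  # compound 400-699
    EXTERNAL = "external"  # compound 700-999

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _route_of_compound(compound: int) -> Route:
    if compound < 400:
        return Route.ORAL
    if compound < 700:
        return Route.INFUSION
    return Route.EXTERNAL


@dataclass(frozen=True)
class MHLWDrugCode:
    """A parsed 12-character MHLW drug code.

    Reassembling ``class4 + compound + form_letter + dose_digit + product``
    reproduces the raw code exactly.
    """

    raw: str
    class4: str       # 4-digit therapeutic class
    class3: str       # 3-digit upper class (prefix of class4)
    compound: str     # 3-digit compound number (route lives in its range)
    route: Route
    form_letter: str  # one upper-case letter (dosage form)
    dose_digit: str   # single digit (dose of one unit)
    product: str      # 3-digit product number

    def reassemble(self) -> str:
        return self.class4 + self.compound + self.form_letter + self.dose_digit + self.product


@dataclass(frozen=True)
class CodeGroupKey:
    """A deterministic grouping key for a code under a compilation scheme."""

    system: str  # "drug" or "icd10"
    key: str


#: Sentinel returned by :func:`icd10_group_key` for nephrology codes that the
#: scheme excludes outright (scheme ``pattern_b`` drops N0xx-N2xx).
NEPHROLOGY_EXCLUDED = object()

_MHLW_RE = re.compile(r"^[0-9]{7}[A-Z][0-9]{4}$")
_ICD10_RE = re.compile(r"^[A-Z][0-9A-Z]{2,3}$")


def parse_mhlw_code(code: str) -> MHLWDrugCode:
    """Parse a 12-character MHLW drug code into its hierarchy fields.

    Raises
    ------
    MalformedCodeError
        If the code is not 12 characters of the form ``DDDDDDDLDDDD``
        (7 digits, one upper-case letter, 4 digits).  The message names
        the first offending position (1-based).
    """
    if not isinstance(code, str) or len(code) != 12:
        raise MalformedCodeError(
            f"MHLW code must be a 12-character string, got {code!r}"
        )
    if not _MHLW_RE.match(code):
        for pos, ch in enumerate(code, start=1):
            if pos <= 7 or pos >= 9:
                if not ch.isdigit():
                    raise MalformedCodeError(
                        f"MHLW code {code!r}: position {pos} must be a digit, got {ch!r}"
                    )
            elif not ("A" <= ch <= "Z"):
                raise MalformedCodeError(
                    f"MHLW code {code!r}: position 8 must be an upper-case letter, got {ch!r}"
                )
        raise MalformedCodeError(f"malformed MHLW code {code!r}")  # pragma: no cover
    compound = code[4:7]
    return MHLWDrugCode(
        raw=code,
        class4=code[:4],
        class3=code[:3],
        compound=compound,
        route=_route_of_compound(int(compound)),
        form_letter=code[7],
        dose_digit=code[8],
        product=code[9:12],
    )


def drug_group_key(code: MHLWDrugCode | str) -> CodeGroupKey:
    """Group a drug by therapeutic class and administration route.

    Drugs sharing the top four class digits and the route form one group;
    the compound, form, dose and product digits are ignored.  The key is
    ``"<class4>:<route>"``, e.g. ``"2171:oral"``.
    """
    if isinstance(code, str):
        code = parse_mhlw_code(code)
    return CodeGroupKey(system="drug", key=f"{code.class4}:{code.route.value}")


def icd10_group_key(code: str, scheme: str):
    """Truncate an ICD-10 code under compilation scheme ``pattern_b`` or
    ``pattern_c``.

    ``pattern_b``
        Non-nephrology codes are keyed by their first two characters
        (``J359`` -> ``J3``); nephrology codes (prefixes N0, N1, N2) return
        :data:`NEPHROLOGY_EXCLUDED`.
    ``pattern_c``
        As ``pattern_b``, but nephrology codes are keyed by their first
        three characters (``N028`` -> ``N02``).

    Returns a :class:`CodeGroupKey`, or :data:`NEPHROLOGY_EXCLUDED`.
    """
    if scheme not in ("pattern_b", "pattern_c"):
        raise ValueError(f"unknown ICD-10 grouping scheme {scheme!r}")
    if not isinstance(code, str) or not _ICD10_RE.match(code):
        raise MalformedCodeError(
            f"not an ICD-10-shaped code (letter + 2-3 alphanumerics): {code!r}"
        )
    nephrology = code[0] == "N" and code[1] in "012"
    if nephrology:
        if scheme == "pattern_b":
            return NEPHROLOGY_EXCLUDED
        return CodeGroupKey(system="icd10", key=code[:3])
    return CodeGroupKey(system="icd10", key=code[:2])


def matches_code_pattern(pattern: str, code: str) -> bool:
    """Match a wildcard code pattern against a code.

    Lower-case ``x`` is a single-character wildcard (it matches any digit
    or letter); every other character matches itself.  A pattern shorter
    than the code is matched as a prefix (implicit trailing wildcards), so
    ``"2171"`` matches any code in class 2171.  A pattern longer than the
    code matches only if the excess characters are all wildcards, so
    ``"N02x"`` matches both the 3-character ``N02`` and the 4-character
    ``N028``.
    """
    if not pattern:
        raise ValueError("empty code pattern")
    if len(pattern) > len(code) and any(p != "x" for p in pattern[len(code):]):
        return False
    return all(p == "x" or p == c for p, c in zip(pattern, code))
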