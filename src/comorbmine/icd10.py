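"""ICD-10 code parsing, normalization, and exclusion rules.

Diagnosis codes are analyzed at the three-character *category* level
(letter + two digits, e.g. ``I63``); the leading letter is the *chapter*.
Fourth-character subdivisions (``I63.9``) carry clinical detail that is
discarded here: categories are the unit used for international reporting
and are what the mining pipeline operates on.

Two exclusion rules remove codes that do not denote a disease or a
classifiable condition:

* chapter-based: codes from the external-cause and health-status chapters
  (V, W, X, Y, Z by default) are dropped;
* description-based: codes whose description contains the standalone word
  "other" (e.g. "Other gastritis") are dropped, because such residual
  categories pool heterogeneous conditions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Icd10Code",
    "Icd10ParseError",
    "ExclusionPolicy",
    "parse_code",
    "is_excluded",
]

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


class Icd10ParseError(ValueError):
    """Raised when a string cannot be normalized to an ICD-10 category."""


@dataclass(frozen=True)
class Icd10Code:
    """A normalized ICD-10 code.

    Attributes
    ----------
    raw : str
        The code as received (e.g. ``"E11.9"``).
    category : str
        Three-character category: one letter followed by two digits.
    chapter : str
        Single uppercase letter, always ``category[0]``.
    """

    raw: str
    category: str
    chapter: str

    def __post_init__(self) -> None:
        if not _CATEGORY_RE.match(self.category):
            raise Icd10ParseError(
                f"invalid ICD-10 category {self.category!r} (from {self.raw!r})"
            )
        if self.chapter != self.category[0]:
            raise Icd10ParseError(
                f"chapter {self.chapter!r} does not match category {self.category!r}"
            )


def parse_code(raw: str) -> Icd10Code:
    """Normalize a raw ICD-10 string to its three-character category.

    Accepts three-character (``"I10"``) and longer (``"I10.0"``, ``"E119"``)
    forms; whitespace is stripped and letters uppercased before the first
    three characters are taken.

    Raises
    ------
    Icd10ParseError
        If the input is empty after trimming or the first three characters
        do not match the letter-digit-digit pattern. The offending value is
        named in the message.
    """
    if raw is None:
        raise Icd10ParseError("ICD-10 code is None")
    cleaned = "".join(str(raw).split()).upper()
    if not cleaned:
        raise Icd10ParseError(f"empty ICD-10 code: {raw!r}")
    category = cleaned[:3]
    if not _CATEGORY_RE.match(category):
        raise Icd10ParseError(
            f"malformed ICD-10 code {raw!r}: {category!r} is not "
            "letter-digit-digit"
        )
    return Icd10Code(raw=str(raw), category=category, chapter=category[0])


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which codes are removed before mining.

    ``excluded_chapters`` drops whole chapters (default: the external-cause
    chapters V, W, X, Y and the health-status chapter Z). The description
    rule drops codes whose free-text description contains
    ``excluded_description_token`` as a standalone word; matching is
    case-insensitive unless ``case_sensitive`` is set.
    """

    excluded_chapters: frozenset[str] = frozenset({"V", "W", "X", "Y", "Z"})
    excluded_description_token: str = "other"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "excluded_chapters", frozenset(c.upper() for c in self.excluded_chapters)
        )

    def _token_re(self) -> re.Pattern[str] | None:
        if not self.excluded_description_token:
            return None
        flags = 0 if self.case_sensitive else re.IGNORECASE
        return re.compile(
            r"\b" + re.escape(self.excluded_description_token) + r"\b", flags
        )


def is_excluded(code: Icd10Code, description: str, policy: ExclusionPolicy | None = None) -> bool:
    """True iff *code* is removed by *policy*.

    A code is excluded when its chapter is in ``policy.excluded_chapters``
    or when *description* contains the policy token as a standalone word
    (so "Other gastritis" matches but "Motherhood-related myalgia" does
    not). An empty description never triggers the token rule.
    """
    if policy is None:
        policy = ExclusionPolicy()
    if code.chapter in policy.excluded_chapters:
        return True
    if description:
        token_re = policy._token_re()
        if token_re is not None and token_re.search(description):
            return True
    return False
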