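"""Domain-label equivalence.

Annotation databases refer to the same protein-domain family under
different labels ("FH2", "FH2 domain", "Formin Homology").  Whether two
labels denote the same family is decided here with a deliberately
conservative word-level rule:

1. each label is tokenized on every non-alphanumeric character and
   lower-cased;
2. generic "trivial" words (*a*, *the*, *domain*, *family*, *like*,
   *member*, *of*, *via*, *within*) are discarded;
3. two labels are equivalent iff any remaining word from one is identical
   to, or contained within, a word from the other.

Containment tolerates one trailing character, which catches
pluralization and common prefixing ("kinases" vs "pkinase" through
their shared "kinase") without stemming or fuzzy matching, which would
produce many false merges.  Pure abbreviations ("fmt" vs "formyltransferase") are not
detectable this way; user-supplied override pairs handle those, and can
also veto spurious matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import re
from typing import FrozenSet, Iterable, Tuple

__all__ = [
    "DEFAULT_TRIVIAL_WORDS",
    "LabelTokenSet",
    "EquivalenceOverrides",
    "NO_OVERRIDES",
    "tokenize_label",
    "words_match",
    "labels_equivalent",
    "multilabel_equivalent",
]

#: Generic words that carry no family identity and are stripped before
#: comparison.  Users can supply their own list (one word per line).
DEFAULT_TRIVIAL_WORDS: FrozenSet[str] = frozenset(
    ("a", "the", "domain", "family", "like", "member", "of", "via", "within")
)

#: Words shorter than this never match by containment: a single letter or
#: digit is a substring of almost any label and would merge everything.
#: Identity matches are unaffected.
MIN_CONTAINMENT_LENGTH = 2

_SPLIT_RE = re.compile(r"[^0-9a-z]+")

OverridePair = Tuple[str, str]


@dataclass(frozen=True)
class LabelTokenSet:
    """A label together with its ordered, filtered word tokens."""

    label: str
    tokens: Tuple[str, ...]


def tokenize_label(
    label: str, trivial_words: FrozenSet[str] = DEFAULT_TRIVIAL_WORDS
) -> LabelTokenSet:
    """Split *label* into lower-case words, dropping trivial ones.

    The delimiter set is "any non-alphanumeric character", so underscores,
    hyphens, spaces, periods and parentheses all separate words.  An empty
    label (or one consisting solely of trivial words) yields an empty
    token tuple and therefore matches nothing.
    """
    return LabelTokenSet(label, _tokens(label, frozenset(trivial_words)))


@lru_cache(maxsize=65536)
def _tokens(label: str, trivial_words: FrozenSet[str]) -> Tuple[str, ...]:
    words = (w for w in _SPLIT_RE.split(label.lower()) if w)
    return tuple(w for w in words if w not in trivial_words)


def words_match(w1: str, w2: str) -> bool:
    """True iff the two lower-case words are identical or one contains the
    other, allowing a single trailing character to be ignored on either
    side ("kinases" matches "pkinase" through their shared "kinase").

    Both the contained word and any trimmed form must be at least
    :data:`MIN_CONTAINMENT_LENGTH` characters, so single letters and
    digits never match by containment.
    """
    if w1 == w2:
        return True
    for a, b in ((w1, w2), (w2, w1)):
        for needle in (a, a[:-1]):
            if len(needle) >= MIN_CONTAINMENT_LENGTH and needle in b:
                return True
    return False


def _canonical_pair(a: str, b: str) -> OverridePair:
    a, b = a.casefold(), b.casefold()
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EquivalenceOverrides:
    """User-declared label relationships that pre-empt token matching.

    ``force_distinct`` wins over ``force_equivalent``, which wins over the
    token rule.  Pairs are unordered and case-insensitive.
    """

    force_equivalent: FrozenSet[OverridePair] = frozenset()
    force_distinct: FrozenSet[OverridePair] = frozenset()

    def __post_init__(self) -> None:
        clash = self.force_equivalent & self.force_distinct
        if clash:
            raise ValueError(
                f"label pairs declared both equivalent and distinct: {sorted(clash)}"
            )

    @classmethod
    def from_pairs(
        cls,
        equivalent: Iterable[Tuple[str, str]] = (),
        distinct: Iterable[Tuple[str, str]] = (),
    ) -> "EquivalenceOverrides":
        return cls(
            force_equivalent=frozenset(_canonical_pair(a, b) for a, b in equivalent),
            force_distinct=frozenset(_canonical_pair(a, b) for a, b in distinct),
        )


NO_OVERRIDES = EquivalenceOverrides()


def labels_equivalent(
    a: str,
    b: str,
    overrides: EquivalenceOverrides = NO_OVERRIDES,
    trivial_words: FrozenSet[str] = DEFAULT_TRIVIAL_WORDS,
) -> bool:
    """Decide whether two domain labels denote the same family.

    Precedence: ``force_distinct`` > ``force_equivalent`` > token match.
    A label with no non-trivial tokens matches nothing unless overridden.
    """
    pair = _canonical_pair(a, b)
    if pair in overrides.force_distinct:
        return False
    if pair in overrides.force_equivalent:
        return True
    trivial = frozenset(trivial_words)
    tokens_a = _tokens(a, trivial)
    tokens_b = _tokens(b, trivial)
    return any(words_match(wa, wb) for wa in tokens_a for wb in tokens_b)


def multilabel_equivalent(
    set_a: Iterable[str],
    set_b: Iterable[str],
    overrides: EquivalenceOverrides = NO_OVERRIDES,
    trivial_words: FrozenSet[str] = DEFAULT_TRIVIAL_WORDS,
) -> bool:
    """True iff any label of one multi-label set is equivalent to any label
    of the other.

    This is what makes the final merging step transitive in effect: a
    merged domain labelled {"abc-atpase", "abc-smc5"} is equivalent to one
    labelled {"abc-smc5", "smc"} through their shared member, even though
    "abc-atpase" and "smc" never match directly.
    """
    labels_b = tuple(set_b)
    return any(
        labels_equivalent(la, lb, overrides, trivial_words)
        for la in set_a
        for lb in labels_b
    )
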