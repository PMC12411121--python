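"""Name cleaning and canonicalization.

Two distinct jobs live here:

* the **cleaning cascade**: an ordered sequence of progressively more
  destructive cleaned variants of a verbatim drug name (trailing spaces and
  dots, then special characters and parentheticals, then dosage tokens,
  then route/dose-form tokens). The mapper tries the least-destructive
  variant first, so faithful matches win over aggressive cleaning.

* the **canonical form** used as the lookup key for every name index:
  lowercase, diacritics folded, punctuation collapsed, abbreviations
  expanded, UK spellings unified to US, and tokens sorted. Token sorting
  makes matching invariant to word order ("Oral Tablet Acetaminophen" and
  "Acetaminophen Oral Tablet" collide), which is what an exact-match
  cascade needs in place of a live normalization service.

All pattern and lexicon files are plain delimited text shipped with the
package and overridable per :class:`Normalizer` instance, so the exact
behavior is inspectable and testable.

Deliberately **not** here: fuzzy / edit-distance matching. The cascade is
exact-match based; a misspelled name ("cardiazem" for "cardizem") is meant
to fail.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

# Cleaning-stage labels, in application order.
STAGE_RAW = "RAW"
STAGE_TRIM = "TRIM"
STAGE_SPECIAL_CHARS = "SPECIAL_CHARS"
STAGE_DOSAGE = "DOSAGE"
STAGE_ROUTE = "ROUTE"
STAGES = (STAGE_RAW, STAGE_TRIM, STAGE_SPECIAL_CHARS, STAGE_DOSAGE, STAGE_ROUTE)

# number + unit, optionally with a per-denominator ("5 MG/ML", "10 mg per day")
_DOSE_UNIT = r"(?:mg|mcg|ug|µg|g|kg|ml|l|iu|u|meq|mmol|units?|%)"
_DOSAGE_RE = re.compile(
    rf"\b\d+(?:[.,]\d+)?\s*{_DOSE_UNIT}(?:\s*(?:/|per\s+)\s*(?:{_DOSE_UNIT}|day|dose|hr|h|week))?(?=\s|$|[).,;])",
    re.IGNORECASE,
)

_PAREN_RE = re.compile(r"\([^()]*\)|\[[^\[\]]*\]")
# keep letters, digits, whitespace, and the chars that carry dosage meaning
_SPECIAL_RE = re.compile(r"[^0-9A-Za-z\s.%/]")
_WS_RE = re.compile(r"\s+")
_PUNCT_TO_SPACE_RE = re.compile(r"[^0-9a-z\s]")


def _read_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _read_pairs(text: str) -> dict[str, str]:
    pairs: dict[str, str] = {}
    rows = _read_lines(text)
    for row in rows[1:]:  # first row is the header
        left, _, right = row.partition("\t")
        pairs[left.strip().lower()] = right.strip().lower()
    return pairs


def _load_data_text(name: str) -> str:
    return (resources.files("faersnorm.data") / name).read_text(encoding="utf-8")


def _fold_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


@dataclass(frozen=True)
class CleaningStage:
    ordinal: int
    label: str
    transform: Callable[[str], str]


class Normalizer:
    """Holds the lexicons and implements cascade + canonical form.

    Parameters are file paths overriding the shipped data files; each file
    is one lexicon (see ``faersnorm/data/``).
    """

    def __init__(
        self,
        route_strip_path: str | Path | None = None,
        abbreviations_path: str | Path | None = None,
        spelling_path: str | Path | None = None,
        stopwords_path: str | Path | None = None,
    ) -> None:
        def load(path, default_name):
            if path is not None:
                return Path(path).read_text(encoding="utf-8")
            return _load_data_text(default_name)

        self.route_tokens = {
            t.lower() for t in _read_lines(load(route_strip_path, "route_strip.txt"))
        }
        self.abbreviations = _read_pairs(load(abbreviations_path, "abbreviations.tsv"))
        self.spellings = _read_pairs(load(spelling_path, "spelling_variants.tsv"))
        self.stopwords = {
            t.lower() for t in _read_lines(load(stopwords_path, "stopwords.txt"))
        }
        self._close_token_maps()
        self.stages = (
            CleaningStage(0, STAGE_RAW, lambda s: s.strip()),
            CleaningStage(1, STAGE_TRIM, self.trim),
            CleaningStage(2, STAGE_SPECIAL_CHARS, self.strip_special),
            CleaningStage(3, STAGE_DOSAGE, self.strip_dosage),
            CleaningStage(4, STAGE_ROUTE, self.strip_route),
        )

    def _close_token_maps(self) -> None:
        # Expansion values must be fixed points of the combined token map,
        # otherwise canonical_form would not be idempotent.
        combined = {**self.spellings, **self.abbreviations}
        for table in (self.abbreviations, self.spellings):
            for key, value in list(table.items()):
                tokens = value.split()
                for _ in range(5):
                    new = [combined.get(t, t) for t in tokens]
                    if new == tokens:
                        break
                    tokens = [t for tok in new for t in tok.split()]
                table[key] = " ".join(tokens)

    # ---- cascade stages -------------------------------------------------

    @staticmethod
    def trim(name: str) -> str:
        """Remove leading/trailing whitespace and trailing dots."""
        return name.strip().rstrip(". \t").strip()

    def strip_special(self, name: str) -> str:
        """Drop parenthetical groups; map other symbols/punctuation to space.

        Characters that carry dosage meaning (``.`` ``%`` ``/``) survive so
        the dosage stage still sees intact tokens like ``0.5%``.
        """
        name = _PAREN_RE.sub(" ", name)
        name = _SPECIAL_RE.sub(" ", name)
        return self.trim(_WS_RE.sub(" ", name))

    def strip_dosage(self, name: str) -> str:
        """Remove number+unit dosage tokens (``500MG``, ``0.5%``, ``5 mg/ml``).

        Bare digits that are part of a name (``VITAMIN B12``) are retained:
        only a number immediately followed by a dose unit is a dosage.
        """
        name = _DOSAGE_RE.sub(" ", name)
        return self.trim(_WS_RE.sub(" ", name))

    def strip_route(self, name: str) -> str:
        """Remove route-of-administration / dose-form tokens (lexicon-based)."""
        kept = [t for t in name.split() if t.lower() not in self.route_tokens]
        return self.trim(" ".join(kept))

    def clean_cascade(self, name: str) -> list[tuple[str, str]]:
        """Ordered (stage label, cleaned string) variants, least destructive
        first. Stages apply cumulatively; consecutive duplicates collapse;
        empty variants are dropped."""
        variants: list[tuple[str, str]] = []
        current = name
        for stage in self.stages:
            current = stage.transform(current)
            if not current:
                break
            if not variants or variants[-1][1] != current:
                variants.append((stage.label, current))
        return variants

    # ---- canonical form -------------------------------------------------

    def canonical_form(self, name: str) -> str:
        """Canonical lookup key: lowercase, diacritics folded, punctuation
        collapsed, abbreviations expanded, UK->US spelling unified, tokens
        sorted lexicographically. Idempotent and word-order invariant."""
        text = _fold_diacritics(name).lower()
        text = _PUNCT_TO_SPACE_RE.sub(" ", text)
        tokens: list[str] = []
        for token in text.split():
            token = self.abbreviations.get(token, token)
            token = " ".join(self.spellings.get(t, t) for t in token.split())
            tokens.extend(token.split())
        return " ".join(sorted(tokens))


_DEFAULT: Normalizer | None = None


def default_normalizer() -> Normalizer:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Normalizer()
    return _DEFAULT


def clean_cascade(name: str) -> list[tuple[str, str]]:
    return default_normalizer().clean_cascade(name)


def strip_dosage(name: str) -> str:
    return default_normalizer().strip_dosage(name)


def strip_route(name: str) -> str:
    return default_normalizer().strip_route(name)


def canonical_form(name: str) -> str:
    return default_normalizer().canonical_form(name)
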