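"""Eligibility-criteria section parsing and concept tagging.

Registry eligibility sections come in three common layouts: an
inclusion/exclusion bullet list, a bullet list grouped under aspect headers
(e.g. "DISEASE CHARACTERISTICS:"), or free-text paragraphs.  The first two
support criterion-level extraction (bullets, numbering and indentation mark
the individual criteria; aspect-list items are all inclusive); free text does
not, so there only whole-section concept tagging applies.

Concept recognition is a pluggable dictionary tagger over a user-supplied
lexicon mapping surface forms to concept identifiers, with an optional flag
marking membership in a clinical-terminology (SNOMED CT-style) subset of the
lexicon.  Matching is greedy longest-match, case-insensitive,
token-boundary-respecting and non-overlapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from ._text import normalize_block, word_token_spans
from .protocol_io import TrialProtocol

__all__ = [
    "SectionFormat",
    "Polarity",
    "CriterionItem",
    "ConceptAnnotation",
    "ConceptLexicon",
    "detect_format",
    "segment_criteria",
    "tag_concepts",
    "concept_facets",
    "CONCEPT_FACET_CATEGORIES",
]

CONCEPT_FACET_CATEGORIES = (
    "concept",
    "SNOMEDCT_concept",
    "inclusion_concept",
    "exclusion_concept",
    "inclusion_SNOMEDCT_concept",
    "exclusion_SNOMEDCT_concept",
)


class SectionFormat(Enum):
    INC_EXC_LIST = "inc_exc_list"
    ASPECT_LIST = "aspect_list"
    FREE_TEXT = "free_text"


class Polarity(Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ConceptAnnotation:
    concept_id: str
    preferred_name: str
    surface: str
    start: int
    end: int
    in_snomed_subset: bool


@dataclass(frozen=True)
class CriterionItem:
    text: str
    polarity: Polarity
    indent_level: int
    concepts: frozenset[ConceptAnnotation] = frozenset()


@dataclass(frozen=True)
class ConceptLexicon:
    """Surface form -> (concept_id, preferred_name, in_snomed_subset).

    Keys are stored lowercased with whitespace collapsed to single spaces.
    A stand-in for a full metathesaurus: users supply whatever subset they
    are licensed for, as TSV (surface, concept_id, preferred_name, snomed 0/1).
    """

    entries: dict[str, tuple[str, str, bool]]

    def __post_init__(self) -> None:
        norm = {}
        for surface, val in self.entries.items():
            key = re.sub(r"\s+", " ", surface.strip().lower())
            if not key:
                raise ValueError("lexicon surface forms must be non-empty")
            norm[key] = val
        object.__setattr__(self, "entries", norm)

    @classmethod
    def from_tsv(cls, path) -> "ConceptLexicon":
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                surface, cid, name, flag = line.split("\t")
                entries[surface] = (cid, name, flag.strip() == "1")
        return cls(entries)

    @property
    def max_tokens(self) -> int:
        return max((k.count(" ") + 1 for k in self.entries), default=0)


# ---------------------------------------------------------------------------
# Layout detection and segmentation

_BULLET_RE = re.compile(r"^(\s*)(?:[-*•]|\d+[.)]|\(\d+\))\s+(.*)$")
_INC_EXC_HEADER_RE = re.compile(r"^\s*(inclusion|exclusion)\s+criteria\s*:?\s*$", re.IGNORECASE)


def _is_aspect_header(line: str) -> bool:
    stripped = line.strip()
    if len(stripped) < 3 or not stripped.endswith(":"):
        return False
    body = stripped[:-1].strip()
    if not body:
        return False
    letters = [c for c in body if c.isalpha()]
    if letters and all(c.isupper() for c in letters):
        return True
    words = body.split()
    return bool(words) and all(w[0].isupper() for w in words if w[0].isalpha())


def detect_format(eligibility_text: str) -> SectionFormat:
    """Classify the section layout.

    Inclusion/exclusion headers followed by bulleted or indented lines win;
    otherwise other colon-terminated all-caps/title-case headers with bullets
    mark an aspect list; everything else (including empty text) is free text.
    """
    lines = normalize_block(eligibility_text).split("\n")
    has_bullets = any(_BULLET_RE.match(ln) for ln in lines)
    if not has_bullets:
        return SectionFormat.FREE_TEXT
    if any(_INC_EXC_HEADER_RE.match(ln) for ln in lines):
        return SectionFormat.INC_EXC_LIST
    if any(_is_aspect_header(ln) and not _INC_EXC_HEADER_RE.match(ln) for ln in lines):
        return SectionFormat.ASPECT_LIST
    return SectionFormat.FREE_TEXT


def _indent_level(ws: str) -> int:
    return len(ws.expandtabs(2)) // 2


def segment_criteria(eligibility_text: str) -> list[CriterionItem]:
    """Split a list-format section into individual criteria.

    Inclusion/exclusion lists assign each leaf bullet the polarity of its
    governing header; aspect lists are all inclusive; free text yields no
    items.  Only deepest-indented (leaf) bullets become criteria — a bullet
    followed by a more-indented bullet is grouping context, not a criterion.
    Non-bullet trailing prose is ignored.
    """
    fmt = detect_format(eligibility_text)
    if fmt is SectionFormat.FREE_TEXT:
        return []
    lines = normalize_block(eligibility_text).split("\n")

    raw: list[tuple[int, str, Polarity]] = []  # (indent, text, polarity)
    polarity = Polarity.INCLUSION
    for ln in lines:
        header = _INC_EXC_HEADER_RE.match(ln)
        if header:
            polarity = (
                Polarity.INCLUSION
                if header.group(1).lower() == "inclusion"
                else Polarity.EXCLUSION
            )
            continue
        if fmt is SectionFormat.ASPECT_LIST and _is_aspect_header(ln):
            polarity = Polarity.INCLUSION
            continue
        m = _BULLET_RE.match(ln)
        if m:
            text = m.group(2).strip()
            if text:
                raw.append((_indent_level(m.group(1)), text, polarity))

    items: list[CriterionItem] = []
    for i, (indent, text, pol) in enumerate(raw):
        is_parent = i + 1 < len(raw) and raw[i + 1][0] > indent
        if not is_parent:
            items.append(CriterionItem(text=text, polarity=pol, indent_level=indent))
    return items


# ---------------------------------------------------------------------------
# Dictionary concept tagging


def tag_concepts(text: str, lexicon: ConceptLexicon) -> set[ConceptAnnotation]:
    """Greedy longest-match dictionary tagging.

    Scans token positions left to right; at each position the longest
    lexicon surface form starting there wins and the scan resumes after it,
    so annotations never overlap and always respect token boundaries.
    """
    if not lexicon.entries:
        return set()
    spans = word_token_spans(text)
    tokens = [re.sub(r"\s+", " ", text[s:e].lower()) for s, e in spans]
    max_len = lexicon.max_tokens
    out: set[ConceptAnnotation] = set()
    i = 0
    while i < len(tokens):
        matched = False
        for j in range(min(len(tokens), i + max_len), i, -1):
            key = " ".join(tokens[i:j])
            entry = lexicon.entries.get(key)
            if entry is not None:
                start, end = spans[i][0], spans[j - 1][1]
                cid, name, snomed = entry
                out.add(
                    ConceptAnnotation(
                        concept_id=cid,
                        preferred_name=name,
                        surface=text[start:end],
                        start=start,
                        end=end,
                        in_snomed_subset=snomed,
                    )
                )
                i = j
                matched = True
                break
        if not matched:
            i += 1
    return out


def concept_facets(
    corpus: list[TrialProtocol], lexicon: ConceptLexicon
) -> dict[str, dict[str, set[str]]]:
    """Per-protocol concept facet sets (concept ids) for all six categories.

    ``concept`` / ``SNOMEDCT_concept`` come from tagging the whole
    eligibility section; the inclusion/exclusion variants from tagging the
    segmented criteria of list-format sections (free-text sections populate
    only the first two).
    """
    out: dict[str, dict[str, set[str]]] = {}
    for p in corpus:
        section = tag_concepts(p.eligibility_text, lexicon)
        concept_ids = {a.concept_id for a in section}
        snomed_ids = {a.concept_id for a in section if a.in_snomed_subset}
        inc_ids: set[str] = set()
        exc_ids: set[str] = set()
        inc_sno: set[str] = set()
        exc_sno: set[str] = set()
        for item in segment_criteria(p.eligibility_text):
            anns = tag_concepts(item.text, lexicon)
            ids = {a.concept_id for a in anns}
            sno = {a.concept_id for a in anns if a.in_snomed_subset}
            if item.polarity is Polarity.EXCLUSION:
                exc_ids |= ids
                exc_sno |= sno
            else:
                inc_ids |= ids
                inc_sno |= sno
            # criterion-level tags are still section occurrences
            concept_ids |= ids
            snomed_ids |= sno
        out[p.id] = {
            "concept": concept_ids,
            "SNOMEDCT_concept": snomed_ids,
            "inclusion_concept": inc_ids,
            "exclusion_concept": exc_ids,
            "inclusion_SNOMEDCT_concept": inc_sno,
            "exclusion_SNOMEDCT_concept": exc_sno,
        }
    return out
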