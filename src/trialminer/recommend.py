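"""Eligibility-criteria recommendation for a selected protocol set.

Given protocols a user selected as similar to the trial they are designing,
every criterion (bullet/sentence) found in the selection's eligibility
sections is scored by the average corpus frequency of the concepts it
contains: the more often a concept occurs in the selection's eligibility
sections, the more important it is, and averaging (rather than summing)
avoids favouring long criteria.  Duplicate criteria are removed; the ranked
list is what a user picks inclusion/exclusion criteria from, and the chosen
texts are concatenated into a plain-text report.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .eligibility import ConceptLexicon, CriterionItem, segment_criteria, tag_concepts
from .protocol_io import TrialProtocol

__all__ = [
    "RankedCriterion",
    "concept_frequencies",
    "score_criteria",
    "generate_report",
]


@dataclass(frozen=True)
class RankedCriterion:
    item: CriterionItem
    score: float
    rank: int


def concept_frequencies(
    selected: list[TrialProtocol], lexicon: ConceptLexicon
) -> Counter:
    """Concept occurrence counts within the eligibility sections of the
    selected protocols (occurrences, not document frequencies)."""
    if not selected:
        raise ValueError("no documents selected")
    counts: Counter = Counter()
    for p in selected:
        for ann in tag_concepts(p.eligibility_text, lexicon):
            counts[ann.concept_id] += 1
        # tag_concepts returns a set of distinct spans; each span is one
        # occurrence, so counting set members counts occurrences
    return counts


def _normalized(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().casefold())


def score_criteria(
    selected: list[TrialProtocol], lexicon: ConceptLexicon
) -> list[RankedCriterion]:
    """Pool, score, deduplicate and rank the selection's criteria.

    score(item) = mean of the selection-wide frequencies of the concepts the
    item contains; items with no recognized concept score 0 (still shown,
    ranked last).  Duplicates (case-folded, whitespace-collapsed equality)
    keep their first occurrence.  Ties break by score desc, then number of
    contained concepts desc, then criterion text.
    """
    if not selected:
        raise ValueError("no documents selected")
    freqs = concept_frequencies(selected, lexicon)
    seen: set[str] = set()
    scored: list[tuple[float, int, str, CriterionItem]] = []
    for p in selected:
        for item in segment_criteria(p.eligibility_text):
            key = _normalized(item.text)
            if key in seen:
                continue
            seen.add(key)
            anns = tag_concepts(item.text, lexicon)
            ids = {a.concept_id for a in anns}
            score = sum(freqs.get(c, 0) for c in ids) / len(ids) if ids else 0.0
            scored.append(
                (score, len(ids), item.text, CriterionItem(item.text, item.polarity, item.indent_level, frozenset(anns)))
            )
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        RankedCriterion(item=item, score=score, rank=i + 1)
        for i, (score, _, _, item) in enumerate(scored)
    ]


def generate_report(
    chosen_inclusion: list[str], chosen_exclusion: list[str]
) -> str:
    """Concatenate the user's chosen criteria into a plain-text report.

    One "- "-prefixed line per criterion, in the given order; an empty block
    is omitted entirely, and two empty blocks give the empty string.
    """
    blocks: list[str] = []
    if chosen_inclusion:
        blocks.append(
            "Inclusion Criteria:\n" + "\n".join(f"- {t}" for t in chosen_inclusion)
        )
    if chosen_exclusion:
        blocks.append(
            "Exclusion Criteria:\n" + "\n".join(f"- {t}" for t in chosen_exclusion)
        )
    return "\n\n".join(blocks)
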