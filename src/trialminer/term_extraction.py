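"""Multiword term extraction by the C-Value method.

Candidate multiword expressions are selected by a part-of-speech pattern
(default: the classic noun-phrase filter ``(ADJ|NOUN)+ NOUN``) and scored by
termhood.  With f(a) the corpus frequency of candidate a and T_a the set of
distinct longer candidates containing a as a contiguous token subsequence,
the nestedness of a is

    N(a) = f(a)                                 if T_a is empty
    N(a) = f(a) - (1/|T_a|) * sum_{b in T_a} f(b)   otherwise

and the final score weighs in the candidate's token length |a|:

    C-value(a) = log2(|a|) * N(a)

Candidates are processed longest first; only candidates with C-value > 1 are
retained, sorted in decreasing C-value order.  A candidate seen frequently
inside longer candidates is discounted (it is probably a fragment), while one
nested in many *distinct* longer candidates keeps more credit.

The part-of-speech tagger is a pluggable contract (any callable mapping a
token list to a tag list over {ADJ, NOUN, VERB, OTHER}); the shipped default
is a deterministic closed-class-lexicon + suffix-rule tagger.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from ._text import word_tokens
from .protocol_io import TrialProtocol

__all__ = [
    "TaggedToken",
    "CandidateTerm",
    "DefaultTagger",
    "tag_text",
    "extract_candidates",
    "compute_nestedness",
    "compute_cvalue",
    "extract_terms",
    "terms_facet",
    "DEFAULT_POS_PATTERN",
]

TAGSET = ("ADJ", "NOUN", "VERB", "OTHER")

#: classic C-Value noun-phrase candidate filter
DEFAULT_POS_PATTERN = "(ADJ|NOUN)+NOUN"


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    pos: str
    sentence_index: int
    token_index: int


@dataclass(frozen=True)
class CandidateTerm:
    """A scored multiword candidate.

    ``tokens`` are lowercased surfaces; ``f`` the total corpus occurrence
    count (including occurrences inside longer candidates); ``nested_in`` the
    distinct longer candidates containing it; ``nestedness`` N(a) and
    ``cvalue`` the final score.
    """

    tokens: tuple[str, ...]
    f: int
    nested_in: frozenset[tuple[str, ...]]
    nestedness: float
    cvalue: float

    def __str__(self) -> str:  # pragma: no cover - convenience
        return " ".join(self.tokens)


# ---------------------------------------------------------------------------
# Default tagger: closed-class lexicon + suffix rules, deterministic.

_FUNCTION_WORDS = {
    "a", "an", "the", "and", "or", "but", "nor", "of", "in", "on", "at", "to",
    "for", "with", "by", "from", "as", "into", "than", "that", "which", "who",
    "whom", "whose", "this", "these", "those", "it", "its", "their", "his",
    "her", "any", "all", "no", "not", "if", "then", "per", "via", "during",
    "before", "after", "within", "without", "between", "among", "under",
    "over", "above", "below", "more", "most", "less", "least", "other",
    "each", "both", "either", "neither", "such", "so", "too", "very",
    "must", "may", "might", "can", "could", "will", "would", "shall",
    "should", "only", "least",
}

_VERBS = {
    "is", "are", "was", "were", "be", "been", "being", "am", "has", "have",
    "had", "having", "do", "does", "did", "done", "receive", "receives",
    "received", "receiving", "undergo", "undergoes", "underwent", "include",
    "includes", "included", "including", "require", "requires", "required",
    "requiring", "treat", "treats", "treated", "meet", "meets", "met",
    "participate", "provide", "provides", "provided", "give", "gives",
    "given", "use", "uses", "used", "using", "take", "takes", "taken",
    "taking", "show", "shows", "shown", "occur", "occurs", "occurred",
}

# deliberately narrow: broad suffixes like -ent/-ant/-ory mis-tag frequent
# clinical nouns (consent, patient, treatment, history) as adjectives
_ADJ_SUFFIXES = (
    "ous", "ive", "ic", "ical", "al", "ary", "able", "ible", "ful", "less",
)

# suffix rules are heuristics; explicit entries win for common clinical words
_LEXICON = {
    "chronic": "ADJ", "acute": "ADJ", "severe": "ADJ", "mild": "ADJ",
    "moderate": "ADJ", "malignant": "ADJ", "benign": "ADJ", "informed": "ADJ",
    "upper": "ADJ", "lower": "ADJ", "left": "ADJ", "right": "ADJ",
    "primary": "ADJ", "secondary": "ADJ", "advanced": "ADJ",
    "recurrent": "ADJ", "metastatic": "ADJ", "invasive": "ADJ",
    "persistent": "ADJ", "dependent": "ADJ", "independent": "ADJ",
    "pregnant": "ADJ", "resistant": "ADJ", "significant": "ADJ",
    "adjuvant": "ADJ", "concurrent": "ADJ", "stable": "ADJ",
    "cancer": "NOUN", "patient": "NOUN", "patients": "NOUN",
    "hospital": "NOUN", "trial": "NOUN", "animal": "NOUN",
}


class DefaultTagger:
    """Deterministic lexicon + suffix-rule part-of-speech tagger.

    Closed-class (function) words tag OTHER, a small verb lexicon tags VERB,
    adjective-like suffixes tag ADJ, numbers tag OTHER, everything else tags
    NOUN.  Intentionally noun-biased: unknown biomedical vocabulary is far
    more often nominal than not, and the candidate filter downstream only
    keeps noun-phrase shapes.
    """

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self._tag(t) for t in tokens]

    @staticmethod
    def _tag(token: str) -> str:
        low = token.lower()
        if low in _LEXICON:
            return _LEXICON[low]
        if low in _FUNCTION_WORDS:
            return "OTHER"
        if low in _VERBS:
            return "VERB"
        if not any(ch.isalpha() for ch in low):
            return "OTHER"
        for suf in _ADJ_SUFFIXES:
            if len(low) > len(suf) + 2 and low.endswith(suf):
                return "ADJ"
        return "NOUN"


Tagger = Callable[[Sequence[str]], list[str]]

_SENT_SPLIT_RE = re.compile(r"(?<=[.!?;])\s+|\n+")


def tag_text(text: str, tagger: Tagger | None = None) -> list[list[TaggedToken]]:
    """Segment into sentences, tokenize, and tag every token.

    Returns one list of :class:`TaggedToken` per sentence; empty text gives
    an empty list.
    """
    tagger = tagger or DefaultTagger()
    sentences: list[list[TaggedToken]] = []
    for raw in _SENT_SPLIT_RE.split(text or ""):
        tokens = word_tokens(raw)
        if not tokens:
            continue
        tags = tagger(tokens)
        s = len(sentences)
        sentences.append(
            [TaggedToken(tok, tag, s, i) for i, (tok, tag) in enumerate(zip(tokens, tags))]
        )
    return sentences


def extract_candidates(
    tagged: list[list[TaggedToken]],
    pattern: str = DEFAULT_POS_PATTERN,
) -> dict[tuple[str, ...], list[tuple[int, int]]]:
    """Candidate token sequences (length >= 2) matching the PoS pattern.

    Every contiguous within-sentence span whose tag sequence fully matches
    ``pattern`` is emitted — maximal matches and their pattern-satisfying
    sub-spans alike, so nestedness is observable downstream.  Returns a
    mapping from the lowercased token tuple to its (sentence, token) start
    positions (a multiset of occurrences).
    """
    try:
        tag_re = re.compile(pattern.replace(" ", ""))
    except re.error as exc:
        raise ValueError(f"invalid PoS pattern {pattern!r}: {exc}") from exc

    # the pattern is written over concatenated tag names; with this tagset
    # no concatenation is ambiguous, so fullmatch over the joined string
    # decides span membership
    out: dict[tuple[str, ...], list[tuple[int, int]]] = defaultdict(list)
    for sent in tagged:
        tags = [t.pos for t in sent]
        n = len(tags)
        for i in range(n - 1):
            for j in range(i + 2, n + 1):
                if tag_re.fullmatch("".join(tags[i:j])):
                    key = tuple(t.surface.lower() for t in sent[i:j])
                    out[key].append((sent[i].sentence_index, i))
    return dict(out)


def _contiguous_subsequences(seq: tuple[str, ...], min_len: int = 2) -> set[tuple[str, ...]]:
    n = len(seq)
    return {
        seq[i:j]
        for i in range(n)
        for j in range(i + min_len, n + 1)
        if j - i < n  # proper subsequences only
    }


def compute_nestedness(frequencies: dict[tuple[str, ...], int]) -> dict[tuple[str, ...], tuple[float, frozenset]]:
    """Fill N(a) for every candidate given corpus frequencies f(a).

    Returns ``{tokens: (N, T_a)}`` where ``T_a`` is the frozenset of distinct
    longer candidates containing ``tokens`` contiguously.
    """
    containers: dict[tuple[str, ...], set[tuple[str, ...]]] = defaultdict(set)
    for cand in frequencies:
        for sub in _contiguous_subsequences(cand):
            if sub in frequencies:
                containers[sub].add(cand)
    out: dict[tuple[str, ...], tuple[float, frozenset]] = {}
    for cand, f in frequencies.items():
        t_a = frozenset(containers.get(cand, ()))
        if not t_a:
            n_val = float(f)
        else:
            n_val = f - sum(frequencies[b] for b in t_a) / len(t_a)
        out[cand] = (n_val, t_a)
    return out


def compute_cvalue(frequencies: dict[tuple[str, ...], int]) -> list[CandidateTerm]:
    """Rank candidates by C-value, longest first, strict > 1 threshold.

    Output is sorted by C-value descending, then token length descending,
    then lexicographically — a total, deterministic order.
    """
    nested = compute_nestedness(frequencies)
    terms: list[CandidateTerm] = []
    # longest-first processing order per the method's definition
    for cand in sorted(frequencies, key=lambda c: (-len(c), c)):
        n_val, t_a = nested[cand]
        cv = math.log2(len(cand)) * n_val
        if cv > 1.0:
            terms.append(
                CandidateTerm(
                    tokens=cand,
                    f=frequencies[cand],
                    nested_in=t_a,
                    nestedness=n_val,
                    cvalue=cv,
                )
            )
    terms.sort(key=lambda t: (-t.cvalue, -len(t.tokens), t.tokens))
    return terms


def _protocol_term_sections(p: TrialProtocol) -> str:
    """The textual content terms are mined from: brief summary, detailed
    description and eligibility criteria."""
    return "\n".join((p.brief_summary, p.detailed_description, p.eligibility_text))


def extract_terms(
    texts: Iterable[str],
    tagger: Tagger | None = None,
    pattern: str = DEFAULT_POS_PATTERN,
) -> tuple[list[CandidateTerm], list[Counter]]:
    """Run the full candidate-extraction + C-value pipeline over ``texts``.

    Frequencies are pooled corpus-wide; returns the ranked term list and, per
    input text, a Counter of candidate occurrences (used for per-document
    attribution).
    """
    tagger = tagger or DefaultTagger()
    per_text: list[Counter] = []
    freqs: Counter = Counter()
    for text in texts:
        tagged = tag_text(text, tagger)
        occ = extract_candidates(tagged, pattern)
        counts = Counter({cand: len(pos) for cand, pos in occ.items()})
        per_text.append(counts)
        freqs.update(counts)
    return compute_cvalue(dict(freqs)), per_text


def terms_facet(
    corpus: list[TrialProtocol],
    tagger: Tagger | None = None,
    pattern: str = DEFAULT_POS_PATTERN,
) -> tuple[list[CandidateTerm], dict[str, Counter]]:
    """Corpus-wide ranked term list plus per-protocol term occurrences.

    C-value is computed on the concatenation of each protocol's brief
    summary, detailed description and eligibility section, with frequencies
    pooled across the corpus; each protocol is then annotated with the
    retained terms that occur in it (term string -> occurrence count).
    """
    term_list, per_text = extract_terms(
        (_protocol_term_sections(p) for p in corpus), tagger, pattern
    )
    retained = {t.tokens for t in term_list}
    per_protocol: dict[str, Counter] = {}
    for p, counts in zip(corpus, per_text):
        per_protocol[p.id] = Counter(
            {" ".join(cand): c for cand, c in counts.items() if cand in retained}
        )
    return term_list, per_protocol
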