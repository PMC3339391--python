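"""Full-text index with faceted narrowing and a selection board.

A small in-memory inverted index over the protocols' textual fields (title,
brief summary, detailed description, eligibility section), with fourteen
facet categories: seven straight from XML fields, one for extracted
multiword terms, and six for concepts found in the (inclusion/exclusion)
eligibility criteria.  Queries are conjunctive (all tokens must occur);
results are ordered by total query-token frequency, then id.  Facet
narrowing is pure set intersection, so it is monotone, commutative and
idempotent, and can be applied iteratively until the result set satisfies
the user.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from ._text import index_tokens
from .protocol_io import TrialProtocol, extract_facets, protocol_from_dict, protocol_to_dict

__all__ = [
    "Index",
    "ResultSet",
    "SelectionBoard",
    "ALL_FACET_CATEGORIES",
    "build_index",
    "query",
    "narrow",
    "facet_counts",
    "board_add",
    "board_remove",
]

ALL_FACET_CATEGORIES = (
    "phase",
    "condition",
    "intervention_name",
    "intervention_type",
    "authority",
    "study_type",
    "country",
    "termine_term",
    "concept",
    "SNOMEDCT_concept",
    "inclusion_concept",
    "exclusion_concept",
    "inclusion_SNOMEDCT_concept",
    "exclusion_SNOMEDCT_concept",
)

_INDEXED_TEXT_FIELDS = ("title", "brief_summary", "detailed_description", "eligibility_text")


@dataclass
class Index:
    postings: dict[str, set[str]]
    facet_tables: dict[str, dict[str, set[str]]]
    store: dict[str, TrialProtocol]
    token_counts: dict[str, Counter] = field(default_factory=dict)  # id -> token freq


@dataclass(frozen=True)
class ResultSet:
    ids: tuple[str, ...]
    query_trace: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionBoard:
    ids: tuple[str, ...] = ()


def build_index(
    corpus: list[TrialProtocol],
    term_occurrences: dict[str, Counter] | None = None,
    concept_facet_sets: dict[str, dict[str, set[str]]] | None = None,
) -> Index:
    """Build the in-memory index.

    ``term_occurrences`` (protocol id -> term -> count) feeds the
    ``termine_term`` facet; ``concept_facet_sets`` (protocol id -> category
    -> concept ids) feeds the six concept categories.  All fourteen
    categories are always registered.
    """
    store: dict[str, TrialProtocol] = {}
    postings: dict[str, set[str]] = {}
    token_counts: dict[str, Counter] = {}
    facet_tables: dict[str, dict[str, set[str]]] = {c: {} for c in ALL_FACET_CATEGORIES}

    for p in corpus:
        if p.id in store:
            raise ValueError(f"duplicate protocol id {p.id!r}")
        store[p.id] = p
        counts: Counter = Counter()
        for f in _INDEXED_TEXT_FIELDS:
            counts.update(index_tokens(getattr(p, f)))
        token_counts[p.id] = counts
        for tok in counts:
            postings.setdefault(tok, set()).add(p.id)
        for cat, values in extract_facets(p).items():
            for v in values:
                facet_tables[cat].setdefault(v, set()).add(p.id)

    for pid, terms in (term_occurrences or {}).items():
        for term in terms:
            facet_tables["termine_term"].setdefault(term, set()).add(pid)
    for pid, cats in (concept_facet_sets or {}).items():
        for cat, values in cats.items():
            for v in values:
                facet_tables[cat].setdefault(v, set()).add(pid)
    return Index(postings=postings, facet_tables=facet_tables, store=store, token_counts=token_counts)


def query(index: Index, text: str) -> ResultSet:
    """Conjunctive full-text query.

    Documents containing *all* query tokens, ordered by descending total
    query-token frequency then id; the empty query matches every document.
    """
    tokens = index_tokens(text)
    if not tokens:
        ids = sorted(index.store)
        return ResultSet(ids=tuple(ids), query_trace=(f"query:{text!r}",))
    matching: set[str] | None = None
    for tok in tokens:
        hit = index.postings.get(tok, set())
        matching = hit if matching is None else matching & hit
        if not matching:
            break
    matching = matching or set()
    ranked = sorted(
        matching,
        key=lambda pid: (-sum(index.token_counts[pid][t] for t in tokens), pid),
    )
    return ResultSet(ids=tuple(ranked), query_trace=(f"query:{text!r}",))


def narrow(index: Index, rs: ResultSet, category: str, value: str) -> ResultSet:
    """Intersect the result set with one facet value (order-preserving).

    Unknown categories are errors; unknown values give an empty result.
    """
    if category not in ALL_FACET_CATEGORIES:
        raise ValueError(f"unknown facet category {category!r}")
    allowed = index.facet_tables[category].get(value, set())
    return ResultSet(
        ids=tuple(i for i in rs.ids if i in allowed),
        query_trace=rs.query_trace + (f"narrow:{category}={value}",),
    )


def facet_counts(index: Index, rs: ResultSet) -> dict[str, list[tuple[str, int]]]:
    """Facet value counts restricted to the current result set.

    Every category maps to its (value, count) list sorted count-desc then
    value; zero-count values are omitted.
    """
    current = set(rs.ids)
    out: dict[str, list[tuple[str, int]]] = {}
    for cat in ALL_FACET_CATEGORIES:
        counted = [
            (v, len(ids & current))
            for v, ids in index.facet_tables[cat].items()
            if ids & current
        ]
        counted.sort(key=lambda vc: (-vc[1], vc[0]))
        out[cat] = counted
    return out


def board_add(index: Index, board: SelectionBoard, pid: str) -> SelectionBoard:
    """Add a protocol to the selection board (idempotent, order-preserving)."""
    if pid not in index.store:
        raise ValueError(f"unknown protocol id {pid!r}")
    if pid in board.ids:
        return board
    return SelectionBoard(ids=board.ids + (pid,))


def board_remove(board: SelectionBoard, pid: str) -> SelectionBoard:
    """Remove a protocol from the board; absent ids are a no-op."""
    if pid not in board.ids:
        return board
    return SelectionBoard(ids=tuple(i for i in board.ids if i != pid))


# ---------------------------------------------------------------------------
# On-disk form: one JSON file holding the whole index's source of truth
# (the protocol store plus the derived facet tables).


def save_index(index: Index, path) -> None:
    payload = {
        "protocols": [protocol_to_dict(p) for p in sorted(index.store.values(), key=lambda p: p.id)],
        "facets": {
            cat: {v: sorted(ids) for v, ids in sorted(table.items())}
            for cat, table in index.facet_tables.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, sort_keys=True, indent=1)


def load_index(path) -> Index:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    corpus = [protocol_from_dict(d) for d in payload["protocols"]]
    index = build_index(corpus)
    for cat, table in payload["facets"].items():
        for v, ids in table.items():
            index.facet_tables[cat].setdefault(v, set()).update(ids)
    return index
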