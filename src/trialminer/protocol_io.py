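"""Protocol records: XML parsing, facet extraction, (de)serialization and
synthetic corpus generation.

A :class:`TrialProtocol` is one clinical-trial registry record reduced to the
fields the rest of the pipeline consumes: free-text sections (title, brief
summary, detailed description, eligibility criteria) and the structured
metadata fields that become search facets (phase, condition, intervention,
authority, study type, country).  The reference XML dialect is the legacy
ClinicalTrials.gov schema; unknown elements are skipped silently and absent
elements map to empty strings / empty sets.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass

from lxml import etree

from ._text import normalize_block, normalize_inline

__all__ = [
    "TrialProtocol",
    "CorpusSpec",
    "ProtocolParseError",
    "parse_protocol",
    "protocol_to_xml",
    "extract_facets",
    "protocol_to_dict",
    "protocol_from_dict",
    "write_jsonl",
    "read_jsonl",
    "generate_corpus",
    "corpus_truth",
    "planted_eligibility",
]

#: facet categories filled directly from XML fields (the remaining seven of
#: the fourteen categories come from term extraction and concept tagging)
XML_FACET_CATEGORIES = (
    "phase",
    "condition",
    "intervention_name",
    "intervention_type",
    "authority",
    "study_type",
    "country",
)


class ProtocolParseError(ValueError):
    """Raised for malformed protocol XML or a missing registry identifier."""


@dataclass(frozen=True)
class TrialProtocol:
    """One parsed clinical-trial protocol record."""

    id: str
    title: str = ""
    brief_summary: str = ""
    detailed_description: str = ""
    eligibility_text: str = ""
    phase: str = ""
    conditions: frozenset[str] = frozenset()
    intervention_names: frozenset[str] = frozenset()
    intervention_types: frozenset[str] = frozenset()
    authorities: frozenset[str] = frozenset()
    study_type: str = ""
    countries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ProtocolParseError("protocol id must be non-empty")


def _text_of(node: etree._Element | None) -> str:
    if node is None:
        return ""
    return "".join(node.itertext())


def parse_protocol(xml_text: str | bytes) -> TrialProtocol:
    """Parse one protocol XML document into a :class:`TrialProtocol`.

    Raises :class:`ProtocolParseError` for malformed XML or a record without
    an ``nct_id`` element.  Unrecognized elements are ignored; recognized but
    absent elements yield empty values.
    """
    try:
        if isinstance(xml_text, str):
            root = etree.fromstring(xml_text.encode("utf-8"))
        else:
            root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ProtocolParseError(f"malformed protocol XML: {exc}") from exc

    def first(path: str) -> etree._Element | None:
        found = root.findall(path)
        return found[0] if found else None

    pid = _text_of(first(".//nct_id")).strip()
    if not pid:
        raise ProtocolParseError("protocol XML lacks an <nct_id> element")

    return TrialProtocol(
        id=pid,
        title=normalize_inline(_text_of(first(".//brief_title"))),
        brief_summary=normalize_inline(_text_of(first(".//brief_summary/textblock"))),
        detailed_description=normalize_inline(
            _text_of(first(".//detailed_description/textblock"))
        ),
        eligibility_text=normalize_block(
            _text_of(first(".//eligibility/criteria/textblock"))
        ),
        phase=normalize_inline(_text_of(first(".//phase"))),
        conditions=frozenset(
            normalize_inline(_text_of(n)) for n in root.findall(".//condition")
        )
        - {""},
        intervention_names=frozenset(
            normalize_inline(_text_of(n))
            for n in root.findall(".//intervention/intervention_name")
        )
        - {""},
        intervention_types=frozenset(
            normalize_inline(_text_of(n))
            for n in root.findall(".//intervention/intervention_type")
        )
        - {""},
        authorities=frozenset(
            normalize_inline(_text_of(n))
            for n in root.findall(".//oversight_info/authority")
        )
        - {""},
        study_type=normalize_inline(_text_of(first(".//study_type"))),
        countries=frozenset(
            normalize_inline(_text_of(n))
            for n in root.findall(".//location_countries/country")
        )
        - {""},
    )


def protocol_to_xml(p: TrialProtocol) -> str:
    """Serialize a protocol back to the reference XML dialect (UTF-8 string)."""
    root = etree.Element("clinical_study")

    def sub(parent: etree._Element, tag: str, text: str) -> etree._Element:
        node = etree.SubElement(parent, tag)
        node.text = text
        return node

    idinfo = etree.SubElement(root, "id_info")
    sub(idinfo, "nct_id", p.id)
    sub(root, "brief_title", p.title)
    sub(etree.SubElement(root, "brief_summary"), "textblock", p.brief_summary)
    sub(
        etree.SubElement(root, "detailed_description"),
        "textblock",
        p.detailed_description,
    )
    elig = etree.SubElement(root, "eligibility")
    sub(etree.SubElement(elig, "criteria"), "textblock", p.eligibility_text)
    oversight = etree.SubElement(root, "oversight_info")
    for a in sorted(p.authorities):
        sub(oversight, "authority", a)
    sub(root, "phase", p.phase)
    sub(root, "study_type", p.study_type)
    for c in sorted(p.conditions):
        sub(root, "condition", c)
    for name in sorted(p.intervention_names):
        sub(etree.SubElement(root, "intervention"), "intervention_name", name)
    for kind in sorted(p.intervention_types):
        sub(etree.SubElement(root, "intervention"), "intervention_type", kind)
    loc = etree.SubElement(root, "location_countries")
    for c in sorted(p.countries):
        sub(loc, "country", c)
    return etree.tostring(root, encoding="unicode", pretty_print=True)


def extract_facets(p: TrialProtocol) -> dict[str, set[str]]:
    """Facet values contributed directly by XML fields.

    Always returns all seven XML-field categories; empty fields give empty
    sets.  Term and concept facets are contributed by the term-extraction and
    eligibility modules.
    """
    return {
        "phase": {p.phase} - {""},
        "condition": set(p.conditions),
        "intervention_name": set(p.intervention_names),
        "intervention_type": set(p.intervention_types),
        "authority": set(p.authorities),
        "study_type": {p.study_type} - {""},
        "country": set(p.countries),
    }


# ---------------------------------------------------------------------------
# JSON-lines serialization


_SET_FIELDS = ("conditions", "intervention_names", "intervention_types", "authorities", "countries")


def protocol_to_dict(p: TrialProtocol) -> dict:
    d = {
        "id": p.id,
        "title": p.title,
        "brief_summary": p.brief_summary,
        "detailed_description": p.detailed_description,
        "eligibility_text": p.eligibility_text,
        "phase": p.phase,
        "study_type": p.study_type,
    }
    for f in _SET_FIELDS:
        d[f] = sorted(getattr(p, f))
    return d


def protocol_from_dict(d: dict) -> TrialProtocol:
    kwargs = dict(d)
    for f in _SET_FIELDS:
        kwargs[f] = frozenset(kwargs.get(f, ()))
    return TrialProtocol(**kwargs)


def write_jsonl(corpus: list[TrialProtocol], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus:
            fh.write(json.dumps(protocol_to_dict(p), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_jsonl(path) -> list[TrialProtocol]:
    corpus = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                corpus.append(protocol_from_dict(json.loads(line)))
    return corpus


# ---------------------------------------------------------------------------
# Synthetic corpus generation


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a synthetic protocol corpus with known cluster structure.

    Each of ``n_clusters`` topical clusters owns a word vocabulary and a set
    of concept surface forms; documents of a cluster draw body tokens from
    their cluster's vocabulary, with a ``noise_rate`` fraction drawn from the
    ``shared_vocabulary`` instead.  Eligibility sections are emitted as an
    inclusion/exclusion list embedding the cluster's concept surface forms, so
    downstream parsing can be checked against planted ground truth.
    """

    n_clusters: int
    docs_per_cluster: int
    vocabulary_per_cluster: tuple[tuple[str, ...], ...]
    shared_vocabulary: tuple[str, ...] = ()
    concepts_per_cluster: tuple[tuple[str, ...], ...] = ()
    seed: int = 0
    noise_rate: float = 0.0
    body_tokens: int = 80

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.docs_per_cluster < 1:
            raise ValueError("n_clusters and docs_per_cluster must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if len(self.vocabulary_per_cluster) != self.n_clusters:
            raise ValueError("need one vocabulary per cluster")
        if self.concepts_per_cluster and len(self.concepts_per_cluster) != self.n_clusters:
            raise ValueError("need one concept set per cluster (or none)")
        if self.noise_rate == 0.0:
            seen: set[str] = set()
            for vocab in self.vocabulary_per_cluster:
                overlap = seen & set(vocab)
                if overlap:
                    raise ValueError(
                        f"cluster vocabularies overlap at noise_rate=0: {sorted(overlap)}"
                    )
                seen |= set(vocab)


_PHASES = ("1", "2", "3", "4")
_COUNTRIES = ("United States", "United Kingdom", "Canada", "Germany", "Japan")


def planted_eligibility(spec: CorpusSpec, cluster: int) -> tuple[list[str], list[str]]:
    """Ground-truth criterion texts planted in every document of ``cluster``.

    Returns ``(inclusion_texts, exclusion_texts)``.  All concept surface
    forms of the cluster appear in inclusion bullets; the last one also forms
    the single exclusion bullet, so exclusion facets have known content too.
    """
    concepts = list(spec.concepts_per_cluster[cluster]) if spec.concepts_per_cluster else []
    inclusion = [f"Diagnosis of {c}" for c in concepts]
    if not inclusion:
        inclusion = ["Age 18 years or older"]
    exclusion = [f"Prior treatment for {concepts[-1]}"] if concepts else ["Pregnancy"]
    return inclusion, exclusion


def _eligibility_section(spec: CorpusSpec, cluster: int) -> str:
    inclusion, exclusion = planted_eligibility(spec, cluster)
    lines = ["Inclusion Criteria:"]
    lines += [f"  - {t}" for t in inclusion]
    lines.append("Exclusion Criteria:")
    lines += [f"  - {t}" for t in exclusion]
    return "\n".join(lines)


_CONNECTORS = ("of", "in", "with", "for", "and", "after", "during")


def _body(rng: random.Random, spec: CorpusSpec, vocab: tuple[str, ...], n: int) -> str:
    """Draw roughly ``n`` body tokens: cluster words and planted two-word
    phrases joined by function words, with a noise_rate fraction of content
    tokens drawn from the shared vocabulary.

    The function-word connectors keep the prose realistic and stop the
    noun-phrase candidate filter from spanning unrelated content words, so
    the candidate terms a run discovers are the planted phrases.
    """
    phrases = [(vocab[i], vocab[i + 1]) for i in range(0, len(vocab) - 1, 2)]
    units: list[list[str]] = []
    count = 0
    while count < n:
        if spec.shared_vocabulary and rng.random() < spec.noise_rate:
            unit = [rng.choice(spec.shared_vocabulary)]
        elif phrases and rng.random() < 0.5:
            unit = list(rng.choice(phrases))
        else:
            unit = [rng.choice(vocab)]
        units.append(unit)
        count += len(unit)
    sentences = []
    for i in range(0, len(units), 5):
        chunk = units[i : i + 5]
        parts: list[str] = []
        for j, unit in enumerate(chunk):
            if j:
                parts.append(rng.choice(_CONNECTORS))
            parts.extend(unit)
        sentences.append(" ".join(parts) + ".")
    return " ".join(sentences)


def generate_corpus(spec: CorpusSpec) -> list[TrialProtocol]:
    """Generate a synthetic corpus: ``n_clusters * docs_per_cluster`` protocols,
    deterministically from the spec (seed included)."""
    rng = random.Random(spec.seed)
    corpus: list[TrialProtocol] = []
    for c in range(spec.n_clusters):
        vocab = tuple(spec.vocabulary_per_cluster[c])
        for d in range(spec.docs_per_cluster):
            pid = f"NCT{c:03d}{d:05d}"
            corpus.append(
                TrialProtocol(
                    id=pid,
                    title=" ".join(rng.choice(vocab) for _ in range(3)),
                    brief_summary=_body(rng, spec, vocab, spec.body_tokens // 2),
                    detailed_description=_body(rng, spec, vocab, spec.body_tokens),
                    eligibility_text=_eligibility_section(spec, c),
                    phase=_PHASES[c % len(_PHASES)],
                    conditions=frozenset({f"condition {c}"}),
                    intervention_names=frozenset({f"agent {c}"}),
                    intervention_types=frozenset({"drug"}),
                    authorities=frozenset({"United States: Food and Drug Administration"}),
                    study_type="interventional",
                    countries=frozenset(
                        {_COUNTRIES[c % len(_COUNTRIES)], _COUNTRIES[(c + d) % len(_COUNTRIES)]}
                    ),
                )
            )
    return corpus


def corpus_truth(corpus: list[TrialProtocol]) -> dict[str, int]:
    """True cluster index for each generated protocol (encoded in its id)."""
    return {p.id: int(p.id[3:6]) for p in corpus}
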