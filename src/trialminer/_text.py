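"""Shared text normalization and tokenization helpers."""

from __future__ import annotations

import re
import unicodedata

# word tokens: alphanumeric runs, optionally joined by internal hyphens/apostrophes
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*")


def normalize_inline(text: str) -> str:
    """NFC-normalize, convert CRLF to LF and trim every line.

    Used for title/summary/description fields where indentation carries no
    meaning.
    """
    text = unicodedata.normalize("NFC", text or "")
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    lines = [ln.strip() for ln in text.split("\n")]
    while lines and not lines[0]:
        lines.pop(0)
    while lines and not lines[-1]:
        lines.pop()
    return "\n".join(lines)


def normalize_block(text: str) -> str:
    """NFC-normalize, CRLF->LF, trim trailing whitespace per line and remove
    the common leading indent, keeping relative indentation intact.

    Used for the eligibility section, whose bullet structure is
    indentation-sensitive.
    """
    text = unicodedata.normalize("NFC", text or "")
    text = text.replace("\r\n", "\n").replace("\r", "\n").expandtabs(2)
    lines = [ln.rstrip() for ln in text.split("\n")]
    while lines and not lines[0]:
        lines.pop(0)
    while lines and not lines[-1]:
        lines.pop()
    indents = [len(ln) - len(ln.lstrip(" ")) for ln in lines if ln]
    common = min(indents, default=0)
    return "\n".join(ln[common:] if ln else "" for ln in lines)


def word_tokens(text: str) -> list[str]:
    """Tokenize into word strings (original case preserved)."""
    return _TOKEN_RE.findall(text)


def word_token_spans(text: str) -> list[tuple[int, int]]:
    """Token (start, end) character offsets, 0-based half-open."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


def index_tokens(text: str, min_len: int = 2) -> list[str]:
    """Search-index tokenization: lowercase, split on non-alphanumerics,
    keep tokens of length >= ``min_len``."""
    return [t for t in re.split(r"[^a-z0-9]+", text.lower()) if len(t) >= min_len]
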