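"""Concept recognition stand-ins: dictionary tagging, entity masks, markers.

Production GOA curation pipelines identify gene, GO and other biomedical
concept mentions with dedicated NER services.  This module provides an
offline dictionary matcher with the same downstream contract (character-offset
spans with a concept type and an optional normalized id), plus the two ways
the classifier consumes spans:

* a binary *entity mask* aligned to a tokenization — token ``i`` is 1 iff its
  character interval overlaps any span (e.g. tokens ``[ClpXP, degradation,
  machine]`` with spans over the first two give ``(1, 1, 0)``);
* *entity reformulation* — wrapping each span in typed linguistic markers
  such as ``[GENE] … [/GENE]`` directly in the text.

Precomputed spans from a real tagger can be passed anywhere spans are
accepted; nothing downstream depends on how spans were produced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

CONCEPT_TYPES = ("gene", "go", "disease", "chemical", "species", "mutation", "cell_line")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open character span ``[start, end)`` of one concept mention."""

    start: int
    end: int
    concept_type: str
    matched_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.concept_type not in CONCEPT_TYPES:
            raise ValueError(f"unknown concept type {self.concept_type!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def tag_mentions(
    text: str, lexicon: Mapping[str, tuple[str, str]]
) -> list[EntitySpan]:
    """Case-insensitive, word-boundary anchored dictionary matching.

    ``lexicon`` maps a surface string to ``(matched_id, concept_type)``.
    Overlapping candidate matches are resolved longest-span-first, ties by
    earlier start, so "feeding behavior" beats its substring "behavior".
    Returns non-overlapping spans sorted by start offset.
    """
    if not text or not lexicon:
        return []
    candidates: list[EntitySpan] = []
    for surface, (matched_id, ctype) in lexicon.items():
        if not surface:
            continue
        pattern = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(surface) + r"(?![A-Za-z0-9])",
            re.IGNORECASE,
        )
        for m in pattern.finditer(text):
            candidates.append(
                EntitySpan(m.start(), m.end(), ctype, matched_id)
            )
    # longest first, then earliest, then stable by type for determinism
    candidates.sort(key=lambda s: (-(s.end - s.start), s.start, s.concept_type))
    chosen: list[EntitySpan] = []
    for cand in candidates:
        if not any(cand.overlaps(c.start, c.end) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda s: s.start)
    return chosen


_TOKEN_RE = re.compile(r"[A-Za-z0-9_:/\-]+")


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Simple alphanumeric tokenizer returning ``(token, start, end)`` triples."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def build_entity_mask(
    text: str,
    spans: Sequence[EntitySpan],
    tokenization: Sequence[tuple[str, int, int]],
) -> list[int]:
    """Binary mask over tokens: 1 iff the token's interval overlaps any span."""
    n = len(text)
    for tok, start, end in tokenization:
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"token {tok!r} offsets [{start}, {end}) fall outside the text"
            )
    return [
        1 if any(s.overlaps(start, end) for s in spans) else 0
        for _tok, start, end in tokenization
    ]


DEFAULT_MARKERS = {ct: (f"[{ct.upper()}]", f"[/{ct.upper()}]") for ct in CONCEPT_TYPES}


def reformulate_entities(
    text: str,
    spans: Sequence[EntitySpan],
    marker_scheme: Mapping[str, tuple[str, str]] | None = None,
) -> str:
    """Wrap each span in type-specific markers; text outside spans untouched.

    ``"RHO-1 binds GTP"`` with a gene span on RHO-1 becomes
    ``"[GENE] RHO-1 [/GENE] binds GTP"``.  Overlapping spans are rejected.
    """
    markers = DEFAULT_MARKERS if marker_scheme is None else marker_scheme
    ordered = sorted(spans, key=lambda s: s.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping spans [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end}) cannot be reformulated"
            )
    out: list[str] = []
    cursor = 0
    for span in ordered:
        open_m, close_m = markers[span.concept_type]
        out.append(text[cursor : span.start])
        out.append(f"{open_m} {text[span.start:span.end]} {close_m}")
        cursor = span.end
    out.append(text[cursor:])
    return "".join(out)


def strip_markers(
    text: str, marker_scheme: Mapping[str, tuple[str, str]] | None = None
) -> str:
    """Inverse of :func:`reformulate_entities` for marker round-trip checks."""
    markers = DEFAULT_MARKERS if marker_scheme is None else marker_scheme
    for open_m, close_m in markers.values():
        text = text.replace(f"{open_m} ", "").replace(f" {close_m}", "")
    return text


def read_lexicon_tsv(path) -> dict[str, tuple[str, str]]:
    """Read a lexicon ``surface<TAB>id<TAB>type``; later rows win on duplicates."""
    lexicon: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            lexicon[parts[0]] = (parts[1], parts[2])
    return lexicon
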