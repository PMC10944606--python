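"""Normalization: canonical designs, abstract-level unification, hierarchy.

Pipeline for one abstract's mentions:

1. ``canonicalize`` each surface (lowercase, ize->ise spelling, hyphen
   unification, fixed respellings such as "meta analysis" -> "meta-analysis").
2. ``select_representative`` keeps the lengthiest canonical mention — the
   longer the stated design, the more informative it is assumed to be
   ("randomised double blinded controlled trial" beats "randomised
   controlled trial").  Length is measured on the canonical string after
   stripping generic stopwords, so "prospective cohort" beats "cohort
   study".  Ties break to the earliest text position.
3. ``split_design_attributes`` factors the canonical phrase into the
   longest matching lower-level design plus attribute words; unconsumed
   tokens force the miscellaneous node.
4. ``classify_high_level`` maps the lower-level design onto the five
   high-level nodes; ``map_to_hierarchy`` places it on the evidence
   pyramid or labels it unmappable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from .lexicon import MISCELLANEOUS, ClassificationSchema, HierarchyTable, Lexicon
from .rules import DesignMention

__all__ = [
    "HierarchyAssignment",
    "NoDesignError",
    "StandardizedDesign",
    "canonicalize",
    "canonicalize_text",
    "classify_high_level",
    "map_to_hierarchy",
    "select_representative",
    "split_design_attributes",
    "standardize_abstract",
    "standardize_corpus",
]

#: stopwords ignored when comparing mention lengths for representativeness
_LENGTH_STOPWORDS = {"study", "studies", "design", "designs", "of", "a", "an", "the"}

_SPELLING_RE = re.compile(r"iz(e|ed|es|ing|ation|ations)\b")


class NoDesignError(ValueError):
    """No design mention to unify: the abstract is excluded from tallies."""


@dataclass(frozen=True)
class StandardizedDesign:
    """The single representative design retained for one abstract."""

    pmid: str
    representative_surface: str
    canonical: str
    lower_level: str  # "" only when high_level is miscellaneous
    high_level: str
    attributes: frozenset[str]
    all_mentions: tuple[DesignMention, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "pmid": self.pmid,
                "representative_surface": self.representative_surface,
                "canonical": self.canonical,
                "lower_level": self.lower_level,
                "high_level": self.high_level,
                "attributes": sorted(self.attributes),
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "StandardizedDesign":
        d = json.loads(line)
        return cls(
            pmid=str(d["pmid"]),
            representative_surface=d["representative_surface"],
            canonical=d["canonical"],
            lower_level=d["lower_level"],
            high_level=d["high_level"],
            attributes=frozenset(d.get("attributes", [])),
        )


@dataclass(frozen=True)
class HierarchyAssignment:
    pmid: str
    tier: str


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def canonicalize_text(surface: str, schema: ClassificationSchema) -> str:
    """Deterministic canonical form of a design surface string.

    Lowercase, American -ize unified to -ise, hyphens split to spaces, then
    the schema's respell table re-joins fixed compounds ("meta-analysis",
    "nonrandomised") and expands acronyms ("rct").
    """
    text = surface.strip().lower()
    text = re.sub(r"[\s-]+", " ", text)
    text = _SPELLING_RE.sub(lambda m: "is" + m.group(1), text)
    for key in sorted(schema.respell, key=len, reverse=True):
        text = re.sub(rf"\b{re.escape(key)}\b", schema.respell[key], text)
    return re.sub(r"\s+", " ", text).strip()


def canonicalize(mention: DesignMention | str, lexicon: Lexicon) -> str:
    """Canonical design string for a mention (or raw surface string)."""
    surface = mention.surface if isinstance(mention, DesignMention) else mention
    return canonicalize_text(surface, lexicon.schema)


def stripped_length(canonical: str) -> int:
    """Character length of a canonical string minus generic stopwords."""
    kept = [t for t in canonical.split() if t not in _LENGTH_STOPWORDS]
    return len(" ".join(kept))


def select_representative(mentions: list[DesignMention], lexicon: Lexicon) -> DesignMention:
    """The lengthiest-canonical mention; ties break to earliest span start.

    Invariant to the order of the input list.  Raises
    :class:`NoDesignError` on an empty list.
    """
    if not mentions:
        raise NoDesignError("no design mention extracted for this abstract")
    return max(
        mentions,
        key=lambda m: (stripped_length(canonicalize(m, lexicon)), -m.span[0]),
    )


# ---------------------------------------------------------------------------
# design/attribute factoring
# ---------------------------------------------------------------------------

def _attr_phrases(schema: ClassificationSchema, node: str) -> list[tuple[tuple[str, ...], str]]:
    phrases = []
    for attr in schema.attributes.get(node, ()):
        phrases.append((tuple(attr.attribute.split()), attr.attribute))
        for var in attr.variants:
            phrases.append((tuple(var.split()), attr.attribute))
    phrases.sort(key=lambda p: len(p[0]), reverse=True)
    return phrases


def _subsequence_leftover(tokens: list[str], target: tuple[str, ...]) -> list[str] | None:
    """Leftover tokens after removing ``target`` as an in-order subsequence
    (greedy leftmost embedding); None when no embedding exists."""
    leftover = []
    it = 0
    for tok in tokens:
        if it < len(target) and tok == target[it]:
            it += 1
        else:
            leftover.append(tok)
    return leftover if it == len(target) else None


def _consume_leftover(
    leftover: list[str],
    schema: ClassificationSchema,
    node: str,
    *,
    absorb_lowers: bool,
) -> set[str] | None:
    """Consume leftover tokens as attributes of ``node`` plus droppable
    filler (optionally absorbing other same-node lower-level designs).
    Returns the attribute set, or None if any token resists."""
    attrs = _attr_phrases(schema, node)
    same_node_lowers = sorted(
        (tuple(d.split()) for d, n in schema.lower_levels.items() if n == node),
        key=len,
        reverse=True,
    )
    found: set[str] = set()
    i = 0
    while i < len(leftover):
        matched = False
        for phrase, name in attrs:
            if tuple(leftover[i : i + len(phrase)]) == phrase:
                found.add(name)
                i += len(phrase)
                matched = True
                break
        if matched:
            continue
        if leftover[i] in schema.droppable_tokens:
            i += 1
            continue
        if absorb_lowers:
            for phrase in same_node_lowers:
                if tuple(leftover[i : i + len(phrase)]) == phrase:
                    i += len(phrase)
                    matched = True
                    break
            if matched:
                continue
        return None
    return found


def split_design_attributes(
    canonical: str, schema: ClassificationSchema
) -> tuple[str, set[str]]:
    """Factor a canonical phrase into (lower-level design, attribute set).

    Greedy longest lower-level first; leftover tokens must resolve as
    attributes allowed for that design's node or as generic filler.  A
    compound that is itself a listed lower-level ("cross sectional
    descriptive") is never over-factored.  Returns ("", set()) — the
    miscellaneous route — when no factorization consumes every token.
    """
    tokens = canonical.split()
    if not tokens:
        return "", set()
    candidates = sorted(schema.lower_levels, key=lambda d: (-len(d), d))
    embeddings = []
    for design in candidates:
        leftover = _subsequence_leftover(tokens, tuple(design.split()))
        if leftover is not None:
            embeddings.append((design, leftover))
    for absorb in (False, True):
        for design, leftover in embeddings:
            attrs = _consume_leftover(
                leftover, schema, schema.lower_levels[design], absorb_lowers=absorb
            )
            if attrs is not None:
                return design, attrs
    return "", set()


def classify_high_level(lower_level: str, schema: ClassificationSchema) -> str:
    """High-level node for a lower-level design; ambiguous or unknown
    labels (e.g. "analytical study") classify as miscellaneous."""
    if not lower_level:
        return MISCELLANEOUS
    return schema.node_of(lower_level)


def map_to_hierarchy(sd: StandardizedDesign, table: HierarchyTable) -> HierarchyAssignment:
    """Evidence-pyramid tier for a standardized design (miscellaneous and
    unplaced designs get the unmappable label)."""
    if sd.high_level == MISCELLANEOUS or not sd.lower_level:
        return HierarchyAssignment(pmid=sd.pmid, tier=table.unmappable_label)
    return HierarchyAssignment(pmid=sd.pmid, tier=table.tier_of(sd.lower_level))


# ---------------------------------------------------------------------------
# abstract-level unification
# ---------------------------------------------------------------------------

def standardize_abstract(
    mentions: list[DesignMention], lexicon: Lexicon
) -> StandardizedDesign:
    """Unify one abstract's mentions into a single StandardizedDesign."""
    rep = select_representative(mentions, lexicon)
    canonical = canonicalize(rep, lexicon)
    entry = lexicon.lookup(rep.matched_term)
    if entry is not None and entry.miscellaneous:
        lower, attrs = "", set()
    else:
        lower, attrs = split_design_attributes(canonical, lexicon.schema)
    high = classify_high_level(lower, lexicon.schema)
    if high == MISCELLANEOUS:
        lower, attrs = "", set()
    return StandardizedDesign(
        pmid=rep.pmid,
        representative_surface=rep.surface,
        canonical=canonical,
        lower_level=lower,
        high_level=high,
        attributes=frozenset(attrs),
        all_mentions=tuple(mentions),
    )


def standardize_corpus(
    mentions: list[DesignMention], lexicon: Lexicon
) -> list[StandardizedDesign]:
    """One StandardizedDesign per abstract with at least one mention,
    preserving first-seen pmid order."""
    grouped: dict[str, list[DesignMention]] = {}
    for m in mentions:
        grouped.setdefault(m.pmid, []).append(m)
    return [standardize_abstract(ms, lexicon) for ms in grouped.values()]
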