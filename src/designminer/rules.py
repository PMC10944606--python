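"""Rule engine: anchor-pattern matching of study-design mentions.

A rule couples a semi-frozen anchor expression ("we conducted a", "this was
a", "a ... study was performed") with a design slot that must resolve in
the dictionary.  The slot admits attribute words before and inside a
multi-word term, so "we conducted a randomised double blinded controlled
trial" captures the full phrase while the dictionary term is "randomised
controlled trial".  Negative-polarity rules veto positive matches in
prior-study or future-protocol contexts ("six year follow up of a
randomised controlled trial").

Matching is sentence-by-sentence; mentions never cross sentence
boundaries, and identical slot spans matched by several rules collapse to
the lowest (highest-priority) rule id.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .corpus import AbstractRecord
from .lexicon import Lexicon, LexiconEntry, load_lexicon

__all__ = [
    "DesignMention",
    "PatternRule",
    "RuleEngine",
    "RuleError",
    "apply_rules",
    "load_rules",
    "segment_sentences",
    "validate_rules",
]


class RuleError(ValueError):
    """Raised for invalid rule files."""


@dataclass(frozen=True)
class PatternRule:
    rule_id: str
    pattern: str  # regex with {design} (required) and {gap} (optional)
    polarity: str = "positive"  # or "negative"
    window: int = 6  # max tokens between anchor and slot for {gap}
    name: str = ""
    slot_terms: tuple[str, ...] = ()  # optional restriction of the slot

    def __post_init__(self) -> None:
        if self.pattern.count("{design}") != 1:
            raise RuleError(f"rule {self.rule_id}: pattern must use {{design}} exactly once")
        if self.polarity not in ("positive", "negative"):
            raise RuleError(f"rule {self.rule_id}: polarity {self.polarity!r}")
        if self.window < 0:
            raise RuleError(f"rule {self.rule_id}: negative window")


@dataclass(frozen=True)
class DesignMention:
    """A matched design span within one abstract."""

    pmid: str
    surface: str
    span: tuple[int, int]  # 0-based, half-open, over abstract_text
    rule_id: str
    matched_term: str  # dictionary term the slot resolved to
    sentence_index: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "pmid": self.pmid,
                "surface": self.surface,
                "start": self.span[0],
                "end": self.span[1],
                "rule_id": self.rule_id,
                "matched_term": self.matched_term,
                "sentence_index": self.sentence_index,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "DesignMention":
        d = json.loads(line)
        return cls(
            pmid=str(d["pmid"]),
            surface=d["surface"],
            span=(int(d["start"]), int(d["end"])),
            rule_id=d["rule_id"],
            matched_term=d["matched_term"],
            sentence_index=int(d["sentence_index"]),
        )


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "etc", "al", "cf", "ca", "approx",
    "fig", "figs", "no", "dr", "mr", "mrs", "ms", "st",
}
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[\"'(]?[A-Z0-9])")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into ordered, non-overlapping sentence spans.

    Splits on terminal punctuation followed by an upper-case/digit start,
    guarding common abbreviations (``e.g.``, ``vs.``, ``et al.``) and
    single-letter initials.  A final sentence without terminal punctuation
    still gets a span.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        before = text[:m.start()]
        last_word = re.search(r"[\w.]+$", before)
        token = (last_word.group(0) if last_word else "").lower().rstrip(".")
        if token in _ABBREVIATIONS or token.endswith(tuple("." + a for a in _ABBREVIATIONS)):
            continue
        if len(token) == 1 and token.isalpha():  # initials like "J. Smith"
            continue
        end = m.end()
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        spans.append((start + lead, end))
        start = end
    if text[start:].strip():
        chunk = text[start:]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        spans.append((start + lead, len(text) - trail))
    return spans


# ---------------------------------------------------------------------------
# slot regex construction
# ---------------------------------------------------------------------------

_SEP = r"[\s-]+"


def _attr_alternation(lexicon: Lexicon) -> str:
    phrases: set[str] = set()
    for attr in lexicon.attributes:
        phrases.add(attr.attribute)
        phrases.update(attr.variants)
    parts = []
    for phrase in sorted(phrases, key=lambda p: (-len(p), p)):
        toks = [re.escape(t) for t in re.split(r"[ -]+", phrase)]
        parts.append(_SEP.join(toks))
    return "|".join(parts)


def _term_alternation(lexicon: Lexicon, attr_alt: str,
                      slot_terms: tuple[str, ...] = ()) -> str:
    droppable = lexicon.schema.droppable_tokens
    insert = rf"(?:{_SEP}(?:{attr_alt}))*{_SEP}"
    seen: dict[tuple[str, ...], str] = {}
    for variant, entry in lexicon.all_variants().items():
        if slot_terms and entry.term not in slot_terms:
            continue
        toks = tuple(re.split(r"[ -]+", variant))
        seen.setdefault(toks, variant)

    def core_len(toks: tuple[str, ...]) -> int:
        core = list(toks)
        while core and core[-1] in droppable:
            core.pop()
        return len(" ".join(core))

    ordered = sorted(seen, key=lambda t: (-core_len(t), len(t), t))
    parts = []
    for toks in ordered:
        parts.append(insert.join(re.escape(t) for t in toks))
    return "|".join(parts)


def _design_group(lexicon: Lexicon, slot_terms: tuple[str, ...] = ()) -> str:
    attr_alt = _attr_alternation(lexicon)
    term_alt = _term_alternation(lexicon, attr_alt, slot_terms)
    if not term_alt:
        term_alt = r"(?!x)x"  # unreachable slot: matches nothing
    return rf"(?P<design>\b(?:(?:{attr_alt}){_SEP}){{0,3}}(?:{term_alt}))\b"


def _compile_rule(rule: PatternRule, lexicon: Lexicon) -> re.Pattern:
    gap = rf"(?:\S+\s+){{0,{rule.window}}}?"
    pattern = rule.pattern.replace("{gap}", gap)
    pattern = pattern.replace("{design}", _design_group(lexicon, rule.slot_terms))
    return re.compile(pattern, re.IGNORECASE)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class RuleEngine:
    """Compiled rule set bound to one lexicon."""

    def __init__(self, rules: list[PatternRule] | None = None,
                 lexicon: Lexicon | None = None):
        self.lexicon = lexicon if lexicon is not None else load_lexicon()
        self.rules = rules if rules is not None else load_rules()
        ids = [r.rule_id for r in self.rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RuleError(f"duplicate rule ids: {sorted(dupes)}")
        self.positive = sorted(
            (r for r in self.rules if r.polarity == "positive"), key=lambda r: r.rule_id
        )
        self.negative = [r for r in self.rules if r.polarity == "negative"]
        self._compiled = {r.rule_id: _compile_rule(r, self.lexicon) for r in self.rules}
        self._attr_phrases = self._attribute_phrase_tuples()

    def _attribute_phrase_tuples(self) -> list[tuple[str, ...]]:
        phrases = set()
        for attr in self.lexicon.attributes:
            phrases.add(attr.attribute)
            phrases.update(attr.variants)
        return sorted(
            (tuple(re.split(r"[ -]+", p)) for p in phrases), key=len, reverse=True
        )

    def resolve_term(self, phrase: str) -> LexiconEntry | None:
        """Map a matched slot phrase back to its dictionary entry, peeling
        off attribute words that prefix or interleave the term."""
        hit = self.lexicon.lookup(phrase)
        if hit is not None:
            return hit
        tokens = re.split(r"[\s-]+", phrase.strip().lower())
        # remove attribute phrase runs, longest first
        changed = True
        while changed:
            changed = False
            for attr_toks in self._attr_phrases:
                n = len(attr_toks)
                for i in range(len(tokens) - n + 1):
                    if tuple(tokens[i : i + n]) == attr_toks:
                        candidate = " ".join(tokens[:i] + tokens[i + n :])
                        if self.lexicon.lookup(candidate) is not None:
                            return self.lexicon.lookup(candidate)
                        del tokens[i : i + n]
                        changed = True
                        break
                if changed:
                    break
        for i in range(len(tokens)):  # longest suffix fallback
            hit = self.lexicon.lookup(" ".join(tokens[i:]))
            if hit is not None:
                return hit
        return None

    def _matches(self, rules: list[PatternRule], sentence: str,
                 offset: int) -> list[tuple[str, tuple[int, int], str]]:
        found = []
        for rule in rules:
            regex = self._compiled[rule.rule_id]
            pos = 0
            while True:
                m = regex.search(sentence, pos)
                if m is None:
                    break
                start, end = m.span("design")
                found.append((rule.rule_id, (offset + start, offset + end), m.group("design")))
                pos = max(end, m.start() + 1)
        return found

    def extract(self, record: AbstractRecord, *, scan_title: bool = False,
                use_negative: bool = True) -> list[DesignMention]:
        """All positive-rule mentions in a record, after negative vetoes.

        Spans index into ``abstract_text``.  With ``scan_title`` the title
        is scanned as sentence index -1 with spans into the title string.
        """
        mentions: list[DesignMention] = []
        texts = [(record.abstract_text, False)]
        if scan_title and record.title:
            texts.append((record.title, True))
        for text, is_title in texts:
            if not text:
                continue
            for sent_idx, (s_start, s_end) in enumerate(segment_sentences(text)):
                sentence = text[s_start:s_end]
                hits = self._matches(self.positive, sentence, s_start)
                if not hits:
                    continue
                vetoes = (
                    [span for _, span, _ in self._matches(self.negative, sentence, s_start)]
                    if use_negative
                    else []
                )
                by_span: dict[tuple[int, int], tuple[str, str]] = {}
                for rule_id, span, surface in sorted(hits):
                    by_span.setdefault(span, (rule_id, surface))
                # overlapping spans are one occurrence: keep the match from
                # the highest-priority (lowest-id) rule
                chosen: list[tuple[int, int]] = []
                for span in sorted(
                    by_span, key=lambda s: (by_span[s][0], s[0], -(s[1] - s[0]))
                ):
                    if not any(span[0] < e and s < span[1] for s, e in chosen):
                        chosen.append(span)
                for span in sorted(chosen):
                    rule_id, surface = by_span[span]
                    if any(span[0] < v_end and v_start < span[1] for v_start, v_end in vetoes):
                        continue
                    entry = self.resolve_term(surface)
                    if entry is None:
                        continue
                    mentions.append(
                        DesignMention(
                            pmid=record.pmid,
                            surface=surface,
                            span=span,
                            rule_id=rule_id,
                            matched_term=entry.term,
                            sentence_index=-1 if is_title else sent_idx,
                        )
                    )
        return mentions


# ---------------------------------------------------------------------------
# loading / validation / convenience
# ---------------------------------------------------------------------------

def default_rules_path() -> Path:
    return Path(str(resources.files("designminer").joinpath("data/rules.yaml")))


def load_rules(path: str | Path | None = None) -> list[PatternRule]:
    path = default_rules_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not raw or "positive" not in raw:
        raise RuleError(f"{path}: rule file defines no positive rules")
    rules: list[PatternRule] = []
    for polarity in ("positive", "negative"):
        for item in raw.get(polarity) or []:
            rules.append(
                PatternRule(
                    rule_id=item["id"],
                    pattern=item["pattern"],
                    polarity=polarity,
                    window=int(item.get("window", 6)),
                    name=item.get("name", ""),
                    slot_terms=tuple(item.get("slot_terms", ())),
                )
            )
    return rules


def validate_rules(rules: list[PatternRule], lexicon: Lexicon) -> dict:
    """Rule-set health report: counts, unreachable slots, anchor overlaps.

    Duplicate rule ids raise :class:`RuleError`.
    """
    ids = [r.rule_id for r in rules]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise RuleError(f"duplicate rule ids: {dupes}")
    known_terms = {e.term for e in lexicon.entries}
    unreachable = [
        r.rule_id
        for r in rules
        if r.slot_terms and not (set(r.slot_terms) & known_terms)
    ]
    patterns: dict[str, str] = {}
    warnings = []
    for r in rules:
        if r.pattern in patterns:
            warnings.append(
                f"rules {patterns[r.pattern]} and {r.rule_id} share an identical anchor pattern"
            )
        else:
            patterns[r.pattern] = r.rule_id
    return {
        "n_rules": len(rules),
        "n_positive": sum(r.polarity == "positive" for r in rules),
        "n_negative": sum(r.polarity == "negative" for r in rules),
        "unreachable": unreachable,
        "warnings": warnings,
    }


_DEFAULT_ENGINE: RuleEngine | None = None


def default_engine() -> RuleEngine:
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = RuleEngine()
    return _DEFAULT_ENGINE


def apply_rules(record: AbstractRecord, rules: list[PatternRule] | None = None,
                lexicon: Lexicon | None = None, *, scan_title: bool = False,
                use_negative: bool = True) -> list[DesignMention]:
    """Extract design mentions from one record (module-level convenience).

    With default rules and lexicon a shared compiled engine is reused.
    """
    if rules is None and lexicon is None:
        engine = default_engine()
    else:
        engine = RuleEngine(rules=rules, lexicon=lexicon)
    return engine.extract(record, scan_title=scan_title, use_negative=use_negative)
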