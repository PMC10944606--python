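"""Abstract-level evaluation: TP/FP/FN tallies and truncated P/R/F1.

Scoring is per gold design within each abstract: a gold design counts as a
true positive when at least one *related* mention was extracted (canonical
equality or containment — "cohort study" detects "prospective cohort"),
a false negative when every mention of it was missed, and each extracted
design unrelated to any gold design is one false positive.

Precision and recall are percentages *truncated* (not rounded) to one
decimal; the F1 score is the harmonic mean of the truncated precision and
recall, itself truncated to one decimal.  A metric whose denominator is
zero is reported as not applicable (None), never as 0.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction

from .lexicon import Lexicon
from .normalize import canonicalize
from .rounding import trunc1
from .rules import DesignMention

__all__ = [
    "EvalCounts",
    "GoldAnnotation",
    "Metrics",
    "compute_metrics",
    "evaluate_corpus",
    "related",
    "score_abstract",
]


@dataclass(frozen=True)
class GoldAnnotation:
    """Manually annotated designs for one abstract (possibly none)."""

    pmid: str
    gold_designs: frozenset[str]

    def to_json(self) -> str:
        return json.dumps(
            {"pmid": self.pmid, "gold_designs": sorted(self.gold_designs)},
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "GoldAnnotation":
        d = json.loads(line)
        return cls(pmid=str(d["pmid"]), gold_designs=frozenset(d["gold_designs"]))


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("negative evaluation counts")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """One-decimal truncated percentages; None marks an undefined metric."""

    precision: float | None
    recall: float | None
    f1: float | None


_GENERIC = {"study", "studies", "design", "designs", "trial", "trials", "review",
            "reviews", "analysis", "analyses", "a", "an", "the", "of"}

_ATTR_CACHE: dict[int, list[tuple[str, ...]]] = {}


def _attr_phrases(lexicon: Lexicon) -> list[tuple[str, ...]]:
    key = id(lexicon)
    if key not in _ATTR_CACHE:
        phrases: set[str] = set()
        for attr in lexicon.attributes:
            phrases.add(attr.attribute)
            phrases.update(attr.variants)
        _ATTR_CACHE[key] = sorted(
            (tuple(p.split()) for p in phrases), key=len, reverse=True
        )
    return _ATTR_CACHE[key]


def _core_tokens(canonical: str, lexicon: Lexicon) -> tuple[str, ...]:
    """Design core of a canonical phrase: generic head nouns dropped, then
    attribute words removed (falling back to the pre-strip tokens when the
    phrase was nothing but attributes)."""
    toks = [t for t in canonical.split() if t not in _GENERIC]
    if not toks:
        toks = canonical.split()
    stripped = list(toks)
    i = 0
    while i < len(stripped):
        for phrase in _attr_phrases(lexicon):
            if tuple(stripped[i : i + len(phrase)]) == phrase:
                del stripped[i : i + len(phrase)]
                break
        else:
            i += 1
    return tuple(stripped) if stripped else tuple(toks)


def related(a: str, b: str, lexicon: Lexicon) -> bool:
    """Whether two design strings refer to the same study design.

    True on canonical equality or token-boundary containment of design
    cores in either direction (generic head nouns and attribute words set
    aside) — so "cohort study" is related to "prospective cohort"."""
    ca = _core_tokens(canonicalize(a, lexicon), lexicon)
    cb = _core_tokens(canonicalize(b, lexicon), lexicon)
    if ca == cb:
        return True
    shorter, longer = (ca, cb) if len(ca) <= len(cb) else (cb, ca)
    n = len(shorter)
    return any(longer[i : i + n] == shorter for i in range(len(longer) - n + 1))


def _predicted_designs(predicted: list, lexicon: Lexicon) -> list[str]:
    out = []
    for p in predicted:
        canonical = canonicalize(p, lexicon)
        if canonical not in out:
            out.append(canonical)
    return out


def score_abstract(
    gold: GoldAnnotation,
    predicted: list[DesignMention] | list[str],
    lexicon: Lexicon,
) -> EvalCounts:
    """Abstract-level TP/FP/FN for one abstract.

    ``predicted`` may be raw mentions or already-canonical design strings;
    duplicates of one design collapse before counting.
    """
    preds = _predicted_designs(list(predicted), lexicon)
    tp = fn = 0
    for g in gold.gold_designs:
        if any(related(g, p, lexicon) for p in preds):
            tp += 1
        else:
            fn += 1
    fp = sum(
        1 for p in preds if not any(related(g, p, lexicon) for g in gold.gold_designs)
    )
    return EvalCounts(tp=tp, fp=fp, fn=fn)


def compute_metrics(counts: EvalCounts) -> Metrics:
    """Truncated precision/recall/F1 from summed abstract-level counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = trunc1(Fraction(100 * tp, tp + fp)) if tp + fp > 0 else None
    recall = trunc1(Fraction(100 * tp, tp + fn)) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None if precision is None or recall is None else 0.0
    else:
        p = Fraction(precision).limit_denominator(10)
        r = Fraction(recall).limit_denominator(10)
        f1 = trunc1(2 * p * r / (p + r))
    return Metrics(precision=precision, recall=recall, f1=f1)


def evaluate_corpus(
    gold: list[GoldAnnotation],
    predictions: dict[str, list[DesignMention] | list[str]],
    lexicon: Lexicon,
) -> tuple[EvalCounts, Metrics, list[dict]]:
    """Score a whole corpus: counts summed over abstracts, metrics from the
    summed counts, plus a per-abstract decision report for error analysis.

    Every gold pmid must have a predictions entry (an empty list is fine);
    an empty gold set is an error.
    """
    if not gold:
        raise ValueError("empty gold annotation set")
    missing = [g.pmid for g in gold if g.pmid not in predictions]
    if missing:
        raise KeyError(f"gold pmids missing from predictions: {missing[:5]}")
    total = EvalCounts()
    report: list[dict] = []
    for g in gold:
        preds = _predicted_designs(list(predictions[g.pmid]), lexicon)
        counts = score_abstract(g, preds, lexicon)
        total = total + counts
        decisions = []
        for design in sorted(g.gold_designs):
            hits = [p for p in preds if related(design, p, lexicon)]
            decisions.append(
                {"gold": design, "outcome": "TP" if hits else "FN", "mentions": hits}
            )
        for p in preds:
            if not any(related(gd, p, lexicon) for gd in g.gold_designs):
                decisions.append({"gold": None, "outcome": "FP", "mentions": [p]})
        report.append(
            {"pmid": g.pmid, "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
             "decisions": decisions}
        )
    return total, compute_metrics(total), report
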