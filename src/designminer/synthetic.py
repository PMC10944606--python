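"""Gold-annotated synthetic abstract generator.

Emulates the phenomena the extractor must handle in real PubMed prisoner
health abstracts: design statements embedded in anchor phrasings ("we
conducted a ..."), attribute-laden designs ("retrospective cohort",
"randomised double blinded controlled trial"), duplicate full + partial
mentions of one design, adversarial references to *prior* studies ("six
year follow up of a randomised controlled trial") and abstracts that state
no design at all.  Default design and attribute frequencies follow the
head-heavy distribution observed in the discipline; by default about 60 %
of abstracts state no design and about half of the stated designs carry an
attribute.

Every abstract records exactly which designs were injected, so the gold
annotations and the corruption bookkeeping are exact by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .corpus import AbstractRecord, Corpus
from .evaluate import EvalCounts, GoldAnnotation, related
from .lexicon import Lexicon, load_lexicon
from .normalize import canonicalize_text, split_design_attributes

__all__ = ["GeneratorConfig", "SyntheticRecord", "corrupt_predictions", "generate"]

#: lower-level design frequencies observed in the discipline (top designs
#: in a 13,671-abstract sample) — used as default sampling weights
DEFAULT_DESIGN_WEIGHTS: dict[str, int] = {
    "systematic": 1432,
    "randomised controlled": 1136,
    "case report": 806,
    "cross sectional": 634,
    "cohort": 626,
    "randomised": 611,
    "scoping": 202,
    "meta-analysis": 190,
    "descriptive": 157,
    "case control": 123,
    "controlled": 79,
    "survey": 71,
    "cluster randomised controlled": 60,
    "quasi experimental": 52,
    "cluster randomised": 47,
    "meta-analytic": 31,
    "nonrandomised controlled": 23,
    "systematic scoping": 21,
    "cross sectional descriptive": 18,
    "ecological": 13,
    "nonrandomised": 12,
}

#: attribute frequencies by high-level node (trial n=439, observational
#: n=2274 attribute-bearing designs in the same sample)
DEFAULT_ATTRIBUTE_WEIGHTS: dict[str, dict[str, int]] = {
    "trial": {
        "double blind": 149, "pilot": 89, "phase ii": 55, "single blind": 49,
        "phase iii": 49, "phase i": 30, "cost effectiveness": 25,
        "feasibility": 17, "two arm": 16, "superiority": 11,
        "non-inferiority": 11, "efficacy": 8, "equivalence": 3,
        "phase iv": 3, "triple blind": 1,
    },
    "observational": {
        "retrospective": 974, "prospective": 633, "qualitative": 170,
        "population based": 76, "exploratory": 64, "quantitative": 48,
        "nested": 14, "longitudinal": 25, "serial": 4,
    },
    "review": {},
    "meta-analysis": {},
}

_TOPICS = [
    "adult prisoners", "juvenile detainees", "people in custody",
    "recently released offenders", "prison officers", "remand prisoners",
    "incarcerated women", "young offenders",
]
_OUTCOMES = [
    "hepatitis c prevalence", "mental health outcomes", "substance use",
    "self-harm", "vaccination uptake", "smoking cessation",
]
_BACKGROUND = [
    "Health needs in correctional settings remain poorly documented.",
    "Incarcerated populations experience a high burden of chronic disease.",
    "Access to care during imprisonment varies widely between jurisdictions.",
    "Little is known about {outcome} among {topic}.",
]
_RESULTS = [
    "Prevalence estimates were higher among younger detainees.",
    "Participation rates exceeded eighty percent across sites.",
    "Outcomes improved modestly over the observation period.",
    "Rates of {outcome} differed markedly by facility type.",
]
_CONCLUSION = [
    "These findings support improved screening at reception.",
    "Further work should address continuity of care after release.",
    "Service planning should account for the needs of {topic}.",
]

# design-statement templates keyed by the rule each exercises;
# "head" templates take a modifier surface ("cross-sectional"),
# "bare" templates take a full noun phrase ("randomised controlled trial")
_HEAD_TEMPLATES = [
    ("P01", "We conducted {a} {design} study of {outcome} in {topic}."),
    ("P03", "This was {a} {design} study of {outcome} among {topic}."),
    ("P05", "{A} {design} study was conducted among {topic}."),
    ("P09", "In this {design} study, we examined {outcome} in {topic}."),
    ("P10", "This {design} study examined {outcome} among {topic}."),
    ("P20", "The work was {a} {design} study of {outcome}."),
]
_BARE_TEMPLATES = [
    ("P01", "We conducted {a} {design} of {outcome} in {topic}."),
    ("P02", "We report {a} {design} of {outcome} among {topic}."),
    ("P03", "This was {a} {design} of {outcome} among {topic}."),
    ("P06", "{A} {design} was conducted among {topic}."),
    ("P15", "As part of {a} {design}, we interviewed {topic}."),
    ("P18", "{A} {design} of {topic} was undertaken to assess {outcome}."),
]
_PARTIAL_TEMPLATE = ("P16", "Findings from this {design}{head} are reported in full.")
_ADVERSARIAL_TEMPLATE = ("P02", "We report a six year follow up of {a} {design}.")

_NP_LAST_TOKENS = {
    "study", "studies", "trial", "trials", "review", "reviews", "survey",
    "surveys", "analysis", "analyses", "report", "reports", "experiment",
    "experiments", "audit", "audits", "investigation", "investigations",
    "design", "designs", "evaluation", "synthesis", "regression", "rct",
    "rcts", "meta-analysis", "meta-analyses", "series",
}
_ADVERSARIAL_POOL = [
    "randomised controlled trial", "cohort study", "case-control study",
    "cross-sectional survey",
]


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic corpora.

    Defaults mirror the discipline: ~60 % of abstracts state no design,
    ~47.5 % of stated designs carry an attribute, design/attribute draws
    follow the observed frequency tables, and publication years span
    1963–2023.
    """

    n_abstracts: int = 100
    seed: int = 0
    p_no_design: float = 0.6
    p_duplicate_mention: float = 0.25
    p_adversarial: float = 0.15
    p_attribute: float = 0.475
    design_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DESIGN_WEIGHTS)
    )
    attribute_distribution: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ATTRIBUTE_WEIGHTS.items()}
    )
    year_range: tuple[int, int] = (1963, 2023)

    def validate(self, lexicon: Lexicon) -> None:
        for p in (self.p_no_design, self.p_duplicate_mention, self.p_adversarial,
                  self.p_attribute):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.design_distribution or all(
            w <= 0 for w in self.design_distribution.values()
        ):
            raise ValueError("design_distribution needs at least one positive weight")
        unknown = set(self.design_distribution) - set(lexicon.schema.lower_levels)
        if unknown:
            raise ValueError(f"design_distribution names unknown designs: {sorted(unknown)}")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range reversed")


@dataclass
class SyntheticRecord:
    """One generated abstract with its gold annotation and bookkeeping."""

    record: AbstractRecord
    gold: GoldAnnotation
    bookkeeping: dict


def _article(phrase: str) -> str:
    return "an" if phrase[:1].lower() in "aeiou" else "a"


def _is_np(surface: str) -> bool:
    return surface.split(" ")[-1].lower() in _NP_LAST_TOKENS


def _surface_pool(lexicon: Lexicon) -> dict[str, list[str]]:
    """Candidate term surfaces per lower-level design (singular variants,
    attribute-free terms only, so composed attributes stay controlled)."""
    from .lexicon import expand_variants

    pool: dict[str, list[str]] = {}
    for entry in lexicon.entries:
        if entry.miscellaneous or not entry.canonical_design:
            continue
        canonical = canonicalize_text(entry.term, lexicon.schema)
        _, attrs = split_design_attributes(canonical, lexicon.schema)
        if attrs:
            continue  # e.g. "prospective cohort": attribute already baked in
        singular = replace(entry, plural=False)
        pool.setdefault(entry.canonical_design, []).extend(expand_variants(singular))
    return {k: sorted(set(v)) for k, v in pool.items()}


def _compose(
    rng: random.Random,
    lower: str,
    pool: dict[str, list[str]],
    lexicon: Lexicon,
    config: GeneratorConfig,
) -> tuple[str, str, str | None]:
    """Pick a term surface for ``lower`` and optionally weave an attribute
    in, verifying the composed phrase factors back to (lower, {attribute}).
    Returns (composed surface, attribute-free base surface, attribute)."""
    surface = rng.choice(pool[lower])
    node = lexicon.schema.node_of(lower)
    weights = config.attribute_distribution.get(node) or {}
    if not weights or rng.random() >= config.p_attribute:
        return surface, surface, None
    names = sorted(weights)
    for _ in range(5):
        attr = rng.choices(names, weights=[weights[n] for n in names])[0]
        tokens = surface.split(" ")
        if len(tokens) >= 3 and rng.random() < 0.5:
            candidate = " ".join([tokens[0], attr] + tokens[1:])
        else:
            candidate = f"{attr} {surface}"
        canonical = canonicalize_text(candidate, lexicon.schema)
        factored = split_design_attributes(canonical, lexicon.schema)
        if factored == (lower, {attr}):
            return candidate, surface, attr
    return surface, surface, None


def _fill(rng: random.Random, template: str) -> str:
    return template.format(
        topic=rng.choice(_TOPICS), outcome=rng.choice(_OUTCOMES)
    )


def generate(config: GeneratorConfig, lexicon: Lexicon | None = None) -> list[SyntheticRecord]:
    """Generate a reproducible gold-annotated corpus of synthetic abstracts."""
    lexicon = lexicon or load_lexicon()
    config.validate(lexicon)
    rng = random.Random(config.seed)
    designs = sorted(d for d, w in config.design_distribution.items() if w > 0)
    weights = [config.design_distribution[d] for d in designs]
    pool = _surface_pool(lexicon)
    missing = [d for d in designs if not pool.get(d)]
    if missing:
        raise ValueError(f"no attribute-free dictionary surface for designs: {missing}")
    out: list[SyntheticRecord] = []
    for i in range(config.n_abstracts):
        pmid = str(100001 + i)
        topic = rng.choice(_TOPICS)
        outcome = rng.choice(_OUTCOMES)
        sentences = [_fill(rng, rng.choice(_BACKGROUND))]
        phenomena: list[str] = []
        gold: set[str] = set()
        lower = ""
        has_design = rng.random() >= config.p_no_design
        injected_surfaces: list[str] = []
        if has_design:
            lower = rng.choices(designs, weights=weights)[0]
            surface, base, attr = _compose(rng, lower, pool, lexicon, config)
            if attr:
                phenomena.append("attribute")
            templates = _BARE_TEMPLATES if _is_np(surface) else _HEAD_TEMPLATES
            rule_id, template = rng.choice(templates)
            sentence = template.format(
                a=_article(surface), A=_article(surface).capitalize(),
                design=surface, topic=topic, outcome=outcome,
            )
            sentences.append(sentence)
            injected_surfaces.append(surface)
            gold.add(canonicalize_text(surface, lexicon.schema))
            phenomena.append(f"design:{rule_id}")
            if rng.random() < config.p_duplicate_mention:
                # partial repeat: the attribute-free base of the same design
                head = "" if _is_np(base) else " study"
                sentences.append(_PARTIAL_TEMPLATE[1].format(design=base, head=head))
                injected_surfaces.append(base)
                phenomena.append("duplicate")
        else:
            phenomena.append("none")
        sentences.append(_fill(rng, rng.choice(_RESULTS)))
        adversarial_surface = None
        if rng.random() < config.p_adversarial:
            adversarial_surface = next(
                s for s in _ADVERSARIAL_POOL
                if not any(related(s, g, lexicon) for g in gold)
            )
            sentences.append(
                _ADVERSARIAL_TEMPLATE[1].format(
                    a=_article(adversarial_surface), design=adversarial_surface
                )
            )
            phenomena.append("adversarial")
        sentences.append(_fill(rng, rng.choice(_CONCLUSION)))
        record = AbstractRecord(
            pmid=pmid,
            title=f"{outcome.capitalize()} among {topic}: findings from a national sample",
            abstract_text=" ".join(sentences),
            pub_year=rng.randint(*config.year_range),
            pub_types=["Journal Article"],
            language="eng",
        )
        out.append(
            SyntheticRecord(
                record=record,
                gold=GoldAnnotation(pmid=pmid, gold_designs=frozenset(gold)),
                bookkeeping={
                    "phenomena": phenomena,
                    "lower_level": lower,
                    "surfaces": injected_surfaces,
                    "adversarial_surface": adversarial_surface,
                },
            )
        )
    return out


def as_corpus(records: list[SyntheticRecord]) -> Corpus:
    return Corpus(
        records=[r.record for r in records], source_description="synthetic"
    )


_INJECTION_POOL = [
    "ecological study", "mendelian randomisation", "case series",
    "nested case-control study", "meta-analysis",
]


def corrupt_predictions(
    records: list[SyntheticRecord],
    fp_rate: float,
    fn_rate: float,
    seed: int,
    lexicon: Lexicon | None = None,
) -> tuple[dict[str, list[str]], EvalCounts]:
    """Degrade perfect predictions at known rates, returning the exact
    expected abstract-level counts implied by the coin flips.

    Each gold design is dropped with probability ``fn_rate``; with
    probability ``fp_rate`` an unrelated design is injected per abstract.
    """
    if not 0.0 <= fp_rate <= 1.0 or not 0.0 <= fn_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    lexicon = lexicon or load_lexicon()
    rng = random.Random(seed)
    predictions: dict[str, list[str]] = {}
    tp = fp = fn = 0
    for rec in records:
        preds: list[str] = []
        for g in sorted(rec.gold.gold_designs):
            if rng.random() < fn_rate:
                fn += 1
            else:
                preds.append(g)
                tp += 1
        if rng.random() < fp_rate:
            for candidate in _INJECTION_POOL:
                if not any(related(candidate, g, lexicon) for g in rec.gold.gold_designs):
                    preds.append(canonicalize_text(candidate, lexicon.schema))
                    fp += 1
                    break
        predictions[rec.gold.pmid] = preds
    return predictions, EvalCounts(tp=tp, fp=fp, fn=fn)
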