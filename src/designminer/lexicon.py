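"""Study-design dictionary, classification schema and evidence hierarchy.

Everything is loaded from one editable YAML config (the shipped default
carries a 134-term dictionary).  The lexicon owns:

* the design **terms** matched by the rule engine (with automatic
  spelling/hyphen/plural variant expansion),
* the **attribute** vocabulary per high-level node (retrospective,
  double blind, pilot, ...),
* the **classification schema** mapping lower-level designs
  (cohort, randomised controlled, systematic, ...) onto the five
  high-level nodes (observational, trial, review, meta-analysis,
  miscellaneous),
* the **hierarchy table** placing lower-level designs on the pyramid of
  scientific evidence, with an explicit "unmappable" label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "AttributeEntry",
    "ClassificationSchema",
    "HierarchyTable",
    "Lexicon",
    "LexiconEntry",
    "LexiconError",
    "MISCELLANEOUS",
    "expand_variants",
    "load_lexicon",
]

MISCELLANEOUS = "miscellaneous"

#: irregular plurals for head nouns; everything else takes a plain "s"
_PLURALS = {"study": "studies", "analysis": "analyses", "series": "series"}

_SPELLING_RE = re.compile(r"i[sz](e|ed|es|ing|ation|ations)$")


class LexiconError(ValueError):
    """Raised when a lexicon config fails validation."""


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary term with its canonical lower-level design."""

    term: str
    canonical_design: str  # "" when miscellaneous
    miscellaneous: bool = False
    plural: bool = False
    extra_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term or self.term != self.term.strip().lower():
            raise LexiconError(f"term {self.term!r} must be non-empty, lowercase, trimmed")


@dataclass(frozen=True)
class AttributeEntry:
    """One attribute word/phrase and the high-level nodes it may describe."""

    attribute: str
    applies_to: frozenset[str]
    variants: tuple[str, ...] = ()
    dual_role: bool = False  # also listed as a lower-level design label


@dataclass(frozen=True)
class ClassificationSchema:
    """Lower-level design -> high-level node map plus attribute vocabulary."""

    nodes: tuple[str, ...]
    lower_levels: dict[str, str]  # design label -> node
    attributes: dict[str, tuple[AttributeEntry, ...]]  # node -> entries
    droppable_tokens: frozenset[str]
    respell: dict[str, str]

    def node_of(self, lower_level: str) -> str:
        return self.lower_levels.get(lower_level, MISCELLANEOUS)

    def allowed_attributes(self, node: str) -> set[str]:
        return {a.attribute for a in self.attributes.get(node, ())}


@dataclass(frozen=True)
class HierarchyTable:
    """Ordered evidence tiers (top first) and the designs each admits."""

    tiers: tuple[tuple[str, frozenset[str]], ...]
    unmappable_label: str = "unmappable"

    @property
    def tier_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.tiers)

    def tier_of(self, lower_level: str) -> str:
        for name, designs in self.tiers:
            if lower_level in designs:
                return name
        return self.unmappable_label


@dataclass
class Lexicon:
    """Bundle of entries, attributes, schema and hierarchy.

    Iterates as a 4-tuple so callers can unpack
    ``entries, attributes, schema, hierarchy = load_lexicon(...)``.
    """

    entries: list[LexiconEntry]
    attributes: list[AttributeEntry]
    schema: ClassificationSchema
    hierarchy: HierarchyTable
    _by_variant: dict[str, LexiconEntry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for entry in self.entries:
            for variant in expand_variants(entry):
                self._by_variant.setdefault(variant, entry)

    def __iter__(self):
        return iter((self.entries, self.attributes, self.schema, self.hierarchy))

    @property
    def n_design_terms(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> LexiconEntry | None:
        """Resolve a surface string (any known variant) to its entry."""
        key = re.sub(r"\s+", " ", surface.strip().lower())
        hit = self._by_variant.get(key)
        if hit is None:
            hit = self._by_variant.get(key.replace("-", " "))
        return hit

    def all_variants(self) -> dict[str, LexiconEntry]:
        return dict(self._by_variant)


# ---------------------------------------------------------------------------
# variant expansion
# ---------------------------------------------------------------------------

def _spelling_variants(token: str) -> set[str]:
    out = {token}
    m = _SPELLING_RE.search(token)
    if m:
        i = m.start() + 1
        other = "z" if token[i] == "s" else "s"
        out.add(token[:i] + other + token[i + 1 :])
    return out

def _pluralise(token: str) -> str:
    return _PLURALS.get(token, token + "s")

def expand_variants(entry: LexiconEntry) -> list[str]:
    """Closure of a term under spelling (ise/ize), hyphen<->space and, for
    flagged entries, pluralisation of the head noun.  Idempotent: expanding
    any produced variant yields the same set.
    """
    base_forms = {entry.term, *entry.extra_variants}
    if entry.plural:
        for form in list(base_forms):
            parts = re.split(r"([ -])", form)
            parts[-1] = _pluralise(parts[-1])
            base_forms.add("".join(parts))

    variants: set[str] = set()
    for form in base_forms:
        # spelling closure token by token
        token_options = [_spelling_variants(tok) for tok in re.split(r"[ -]+", form)]
        spelled = [""]
        for options in token_options:
            spelled = [f"{acc} {opt}".strip() for acc in spelled for opt in sorted(options)]
        for phrase in spelled:
            toks = phrase.split(" ")
            # hyphen/space closure over every gap
            combos = [toks[0]]
            for tok in toks[1:]:
                combos = [f"{acc}{sep}{tok}" for acc in combos for sep in (" ", "-")]
            variants.update(combos)
    return sorted(variants)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def default_lexicon_path() -> Path:
    return Path(str(resources.files("designminer").joinpath("data/lexicon.yaml")))


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon config (shipped default when ``path`` is
    None).  Duplicate terms, dangling design labels and empty configs are
    load errors, not warnings.
    """
    path = default_lexicon_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not raw or not isinstance(raw, dict):
        raise LexiconError(f"{path}: empty or non-mapping lexicon config")
    for key in ("nodes", "lower_levels", "attributes", "hierarchy", "terms"):
        if key not in raw:
            raise LexiconError(f"{path}: missing required section {key!r}")

    nodes = tuple(raw["nodes"])
    if MISCELLANEOUS not in nodes:
        raise LexiconError(f"{path}: nodes must include {MISCELLANEOUS!r}")

    lower_levels: dict[str, str] = {}
    for node, designs in raw["lower_levels"].items():
        if node not in nodes:
            raise LexiconError(f"{path}: lower_levels references unknown node {node!r}")
        for design in designs:
            if design in lower_levels:
                raise LexiconError(
                    f"{path}: lower-level design {design!r} mapped to more than one node"
                )
            lower_levels[design] = node

    attributes: dict[str, tuple[AttributeEntry, ...]] = {}
    attr_entries: list[AttributeEntry] = []
    merged: dict[str, dict] = {}
    for node, attr_list in raw["attributes"].items():
        if node not in nodes:
            raise LexiconError(f"{path}: attributes reference unknown node {node!r}")
        node_entries = []
        for item in attr_list or []:
            name = item["name"]
            dual = bool(item.get("dual_role"))
            if name in lower_levels and not dual:
                raise LexiconError(
                    f"{path}: attribute {name!r} doubles as a lower-level design "
                    "but is not flagged dual_role"
                )
            entry = AttributeEntry(
                attribute=name,
                applies_to=frozenset({node}),
                variants=tuple(item.get("variants", ())),
                dual_role=dual,
            )
            node_entries.append(entry)
            info = merged.setdefault(
                name, {"nodes": set(), "variants": tuple(entry.variants), "dual": dual}
            )
            info["nodes"].add(node)
        attributes[node] = tuple(node_entries)
    for name, info in merged.items():
        attr_entries.append(
            AttributeEntry(
                attribute=name,
                applies_to=frozenset(info["nodes"]),
                variants=info["variants"],
                dual_role=info["dual"],
            )
        )

    schema = ClassificationSchema(
        nodes=nodes,
        lower_levels=lower_levels,
        attributes=attributes,
        droppable_tokens=frozenset(raw.get("droppable_tokens", ())),
        respell=dict(raw.get("respell", {})),
    )

    hier_raw = raw["hierarchy"]
    tiers = []
    seen_designs: set[str] = set()
    for tier in hier_raw["tiers"]:
        designs = frozenset(tier["designs"])
        overlap = designs & seen_designs
        if overlap:
            raise LexiconError(f"{path}: designs {sorted(overlap)} appear in multiple tiers")
        seen_designs |= designs
        tiers.append((tier["name"], designs))
    hierarchy = HierarchyTable(
        tiers=tuple(tiers), unmappable_label=hier_raw.get("unmappable_label", "unmappable")
    )

    entries: list[LexiconEntry] = []
    seen_terms: set[str] = set()
    for item in raw["terms"]:
        term = item["term"]
        if term in seen_terms:
            raise LexiconError(f"{path}: duplicate term {term!r}")
        seen_terms.add(term)
        misc = bool(item.get("misc"))
        design = item.get("design", "")
        if not misc and design not in lower_levels:
            raise LexiconError(
                f"{path}: term {term!r} names unknown canonical design {design!r}"
            )
        if misc and design:
            raise LexiconError(f"{path}: miscellaneous term {term!r} must have empty design")
        entries.append(
            LexiconEntry(
                term=term,
                canonical_design=design,
                miscellaneous=misc,
                plural=bool(item.get("plural")),
                extra_variants=tuple(item.get("extra_variants", ())),
            )
        )
    if not entries:
        raise LexiconError(f"{path}: lexicon defines no terms")

    return Lexicon(entries=entries, attributes=attr_entries, schema=schema, hierarchy=hierarchy)
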