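# Methods

## The extraction model

designminer treats study-design detection as dictionary-driven pattern
matching rather than statistical NER.  The assumption, which holds well for
epidemiology abstracts, is that authors state their design in a small
number of semi-frozen syntactic frames: a lexical **anchor** ("we conducted
a", "this was a", "a ... study was performed", "STUDY DESIGN:") followed
within a short window by a **design slot** that must resolve in a curated
dictionary.  The package ships 20 positive rules and 3 negative rules as
editable YAML; rules are data, not code.

The design slot is not a flat string match.  It admits up to three
attribute words before the dictionary term and attribute words interleaved
with a multi-word term, so "we conducted a randomised double blinded
controlled trial" yields the full surface while resolving to the dictionary
term *randomised controlled trial*.  Term surfaces are expanded at load
time under three closures — ise/ize spelling, hyphen↔space alternation, and
pluralisation of the head noun for flagged entries — so one entry covers
"case-control", "case control", "case-controls" etc.  Matching is
case-insensitive and sentence-bounded; a small regex sentence splitter with
abbreviation guards ("e.g.", "vs.", "et al.") stands in for a full NLP
pipeline, which this task does not need.

**Negative rules** address the dominant false-positive mode of this kind of
extraction: mentions of *other* studies.  "Six year follow up of a
randomised controlled trial" names a design the present paper did not
implement.  A negative rule's slot match vetoes any positive mention whose
span overlaps it within the same sentence; vetoes can only remove mentions
(monotone suppression, property-tested).  When several positive rules match
the same or overlapping spans of one occurrence, the lowest rule id
(rules are priority-ordered) wins, so each textual occurrence yields one
mention.

## Dictionary, schema, hierarchy

The shipped dictionary holds exactly **134 design terms**.  Its exact
membership is a curated reconstruction: the classification schema's
lower-level designs, the designs observed in published frequency tables
for the prisoner-health literature, and standard epidemiology vocabulary,
including deliberately ambiguous terms ("clinical study", "analytical
study", "systematic approach") that are flagged `misc: true` so they are
*extracted* but classified miscellaneous.  The config is documented as
user-replaceable; every count the package guarantees is validated at load
time, not assumed.

The classification schema maps each lower-level design to exactly one of
five high-level nodes (observational, trial, review, meta-analysis,
miscellaneous) and gives each node an attribute vocabulary (retrospective,
double blind, pilot, ...).  Strings that appear both as a lower-level
design and as an attribute (quantitative, qualitative, comparison, case
series, longitudinal, natural experiment) are flagged `dual_role` in the
config rather than silently resolved.

**Design/attribute factoring** (`split_design_attributes`) factors a
canonical phrase into the longest lower-level design embeddable as an
ordered token subsequence, then requires every leftover token to be an
attribute of that design's node or generic filler (study, trial, of,
clinical, ...).  Candidates that consume everything win over candidates
needing to absorb a second same-node design ("cross sectional survey" →
*cross sectional*), and compounds listed as their own lower level ("cross
sectional descriptive") are never over-factored.  Any unconsumed token
routes the whole phrase to miscellaneous — the package never guesses.

**Abstract-level unification** keeps the *lengthiest* canonical mention per
abstract, on the assumption that the longest stated design is the most
informative.  Length is measured after stripping generic stopwords (study,
design, of, a/an/the) so "prospective cohort" beats "cohort study"; ties
break to the earliest text position, which favours the opening METHODS
statement and keeps the choice deterministic.  All mentions are retained on
the `StandardizedDesign` for audit, so unification loses no information
mechanically rather than by assertion.

**The evidence hierarchy** is an ordered tier table: meta-analysis;
systematic review; randomised controlled trial (including cluster RCTs and
individually randomised trials); controlled & non-randomised trial
(including quasi-experimental and natural experiments); cohort;
case-control; cross-sectional & descriptive (with surveys and ecological
studies); case report & case series.  Everything else — scoping reviews,
bare "randomised" or "cluster randomised" (ambiguous about a control arm),
mendelian randomisation, and all miscellaneous designs — is *unmappable*.
Bare "randomised" is deliberately not credited to the RCT tier: a
"randomised design" statement does not establish a controlled trial.

## Evaluation

Scoring is per gold design per abstract.  A gold design is a TP when at
least one related mention was extracted, an FN when none was; each
predicted design unrelated to every gold design is one FP.  *Related*
means: equal canonical forms, or token-boundary containment of design
cores after setting aside generic head nouns and attribute words — this is
what makes a "cohort study" mention detect the gold design *prospective
cohort*, in either direction.

All percentages use **one-decimal truncation** (floor), with F1 computed
from the *truncated* precision and recall and truncated again.  This is
the unique convention reproducing the published nine-cell benchmark table
(91.17…% must print 91.1), and it is applied uniformly to frequency tables
and trend proportions for internal consistency.  Truncation is computed on
exact rationals (`fractions.Fraction`), so values landing exactly on a
tenth are never floored past it by floating-point noise.  Undefined
metrics (zero denominator) are reported as not-applicable, never 0.0.
One consequence is documented rather than hidden: a source that *rounds* a
small share (190/13,671 = 1.389…% → "1.4") will disagree with this
package's truncated 1.3 by one tenth.

## The synthetic generator

The generator emulates the study conditions of the real literature, not
its language.  Defaults: 60 % of abstracts state no design (the observed
share of abstracts with an extractable design is ~40 %); 47.5 % of stated
designs carry an attribute (the observed share of attribute-bearing
designs); design draws follow the observed head-heavy frequency table
(systematic review and RCT dominating, ecological designs rare) and
attribute draws the observed per-node attribute tables; publication years
span 1963–2023.  A stated design is rendered from a random dictionary
variant (spelling/hyphenation) into one of the anchor frames the rule set
declares; with probability 0.25 the design is mentioned twice, once fully
and once as its attribute-free base; with probability 0.15 an adversarial
"six year follow up of a ⟨unrelated design⟩" sentence is inserted.
Design-free abstracts contain dictionary terms only inside adversarial
contexts or not at all.  A single seeded PRNG drives every draw, so equal
seeds give byte-identical corpora.

Because the generator only emits frames the rules cover, the closed loop
(generate → extract → normalize → evaluate) must score exactly
100.0/100.0/100.0 — and does, on the fixed 500-abstract corpus the tests
use.  Passing therefore shows the pipeline is *internally sound*
(lossless normalization, correct scoring, effective vetoes); it does not
estimate real-world recall, where unseen phrasings and out-of-dictionary
terms ("comprehensive", "steady-state") dominate the error budget.  The
`corrupt_predictions` helper degrades perfect predictions at chosen
FP/FN rates while returning the exact counts implied by its own coin
flips, giving the evaluator an exact oracle.

## Numerical and degenerate-input choices

- Character offsets are 0-based half-open over the concatenated abstract
  text; structured-abstract section labels are kept ("METHODS: ...")
  because anchors legitimately match inside METHODS sections.  Titles are
  not scanned by default; `--scan-titles` opts in (sentence index −1).
- Empty mention lists raise `NoDesignError` from `select_representative`
  (an abstract without mentions is excluded from tallies, not scored 0).
- Duplicate PMIDs within a file de-duplicate to the first occurrence with
  a warning; records without abstracts are counted, not silently dropped.
- Unknown surfaces never crash canonicalization: they route to
  miscellaneous with the raw surface preserved.
- Problem sizes in the shipped tests and acceptance script (500-abstract
  synthetic corpora, 1,000-list permutation property) were chosen to
  exercise every phenomenon class several dozen times while keeping the
  whole suite around half a minute.

## Known limitations

- The 134-term dictionary and the 20-rule set are reconstructions to a
  documented scope, not a copy of any specific supplementary material;
  both files are designed to be swapped out.
- English only, abstract text only; no inference of designs from indirect
  cues (a control group might mean a trial *or* a case-control study —
  the method extracts only explicit design statements).
- Mention-level (span-exact) scoring and inter-annotator workflows are out
  of scope; evaluation is abstract-level by design.
- Live PubMed retrieval is not implemented; the verbatim corpus query is
  shipped as a constant (`pubmed_query()`) for use with external
  E-utilities tooling, and all processing runs on local files.
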