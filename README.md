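# designminer

Rule-based text mining of **epidemiological study designs** in PubMed
abstracts, built for meta-research on justice health / epidemiological
criminology — a field where access barriers make rigorous designs rare and
where knowing *which* designs a literature actually uses matters for its
evidence base.

Given abstracts (PubMed XML, MEDLINE flat text, or JSON-lines), the
package:

1. **detects** design statements with a 134-term design dictionary plus 20
   anchor-pattern rules ("we conducted a *cross-sectional* study", "a
   *randomised controlled trial* of ..."), with negative rules that veto
   references to *prior* studies ("six year follow up of a randomised
   controlled trial");
2. **standardises** mentions (spelling, hyphenation, acronyms), unifies
   multiple mentions per abstract to the *lengthiest* one, and factors each
   canonical design into a lower-level design plus attributes
   ("randomised double blinded controlled trial" → *randomised controlled*
   + {double blind});
3. **classifies** designs into five high-level nodes — observational,
   trial, review, meta-analysis, miscellaneous — and maps them onto the
   hierarchy of scientific evidence (meta-analysis ≻ systematic review ≻
   RCT ≻ ... ≻ case report), labelling ambiguous designs *unmappable*;
4. **evaluates** extraction at the abstract level: a gold design is a TP
   when any *related* mention was found (canonical equality or containment,
   so "cohort study" detects *prospective cohort*), an FN when all its
   mentions were missed, and each unrelated extraction is an FP.  Precision
   and recall are percentages **truncated** (not rounded) to one decimal;
   F1 is the harmonic mean of the truncated values, truncated again;
5. **simulates** gold-annotated corpora so the whole pipeline is testable
   offline, including duplicate/partial mentions, attribute-laden designs
   and adversarial prior-study phrases.

## Worked example

```sh
$ designminer lexicon --validate
design terms: 134
positive rules: 20
negative rules: 3
OK

$ designminer simulate --n 50 --seed 5 --out corpus.jsonl --gold gold.jsonl
simulated 50 abstracts (23 with a design), seed=5

$ designminer extract --in corpus.jsonl --out mentions.jsonl
extracted 31 mentions from 50 abstracts

$ designminer normalize --in mentions.jsonl --out designs.jsonl
standardized 23 abstracts

$ designminer evaluate --gold gold.jsonl --pred mentions.jsonl --report report.csv
TP=23 FP=0 FN=0
precision=100.0 recall=100.0 f1=100.0
```

The 23 abstracts that stated a design were all recovered (31 mentions —
some abstracts repeat their design in full and partial form), none of the
design-free or adversarial abstracts produced a false positive, so all
three truncated metrics print 100.0.  The same works from Python:

```python
from designminer import (AbstractRecord, apply_rules, load_lexicon,
                         standardize_abstract, map_to_hierarchy)

lexicon = load_lexicon()
record = AbstractRecord(pmid="1", abstract_text=(
    "This prospective cohort study examined mortality among inmates. "
    "Findings from this cohort study are reported in full."))
mentions = apply_rules(record)              # "prospective cohort", "cohort"
sd = standardize_abstract(mentions, lexicon)
sd.lower_level, sd.high_level, sd.attributes
# ('cohort', 'observational', frozenset({'prospective'}))
map_to_hierarchy(sd, lexicon.hierarchy).tier
# 'cohort'
```

The evaluation module reproduces a published three-split benchmark of this
extraction approach from its document-level counts — training (TP=75,
FP=4, FN=2) → 94.9 / 97.4 / 96.1, development (62, 6, 3) → 91.1 / 95.3 /
93.1, evaluation (72, 5, 7) → 93.5 / 91.1 / 92.2 — which pins down the
truncation convention exactly (62/68 = 91.17…% must print 91.1).

## Configuration is data

The dictionary, classification schema, attribute vocabulary and evidence
hierarchy live in `src/designminer/data/lexicon.yaml`; the pattern rules in
`src/designminer/data/rules.yaml`.  Both are user-replaceable and
re-validated with `designminer lexicon --validate --lexicon FILE --rules
FILE`.  See `docs/methods.md` for the method, its assumptions and its
limitations.
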