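# Syntactic pattern rules for study-design extraction.
#
# Each rule pairs a semi-frozen anchor expression with one design slot.
# Patterns are Python regular expressions (matched case-insensitively,
# sentence by sentence) with two placeholders:
#   {design}  the design slot: optional attribute words followed by a
#             dictionary term (attribute words may also interleave a
#             multi-word term, e.g. "randomised double blinded controlled
#             trial"); must appear exactly once
#   {gap}     up to `window` arbitrary tokens between anchor and slot
#             (lazy, so attribute words stay inside the slot); default
#             window is 6 tokens
#
# `polarity: negative` rules veto any positive match whose slot overlaps
# theirs within the same sentence (prior-study references, post-hoc
# analyses, future protocols).  Rules are priority-ordered by id: when two
# positive rules capture the same slot span, the lowest id is recorded.
#
# The file is data, not code: edit and re-validate with
# `designminer lexicon --validate --rules FILE`.

version: 1

positive:
  - id: P01
    name: first-person conduct verb
    pattern: '\bwe\s+(?:conducted|performed|undertook|implemented|carried\s+out)\s+(?:a|an|the)\s+{gap}{design}'
    window: 4
  - id: P02
    name: first-person report verb
    pattern: '\bwe\s+(?:report(?:\s+on)?|describe|present)\s+(?:a|an|the)\s+{gap}{design}'
    window: 6
  - id: P03
    name: this was a
    pattern: '\bthis\s+(?:was|is)\s+(?:a|an)\s+{gap}{design}'
    window: 3
  - id: P04
    name: the present study was a
    pattern: '\bthe\s+(?:present|current)\s+(?:study|trial|analysis|article|paper)\s+(?:was|is)\s+(?:a|an)\s+{gap}{design}'
    window: 2
  - id: P05
    name: a design study was conducted
    pattern: '\b(?:a|an)\s+{design}\s+(?:study|trial|survey|analysis|review|design)\s+was\s+(?:conducted|performed|undertaken|carried\s+out|implemented)'
  - id: P06
    name: a design was conducted
    pattern: '\b(?:a|an)\s+{design}\s+was\s+(?:conducted|performed|undertaken|carried\s+out)'
  - id: P07
    name: using a design approach
    pattern: '\busing\s+(?:a|an)\s+{design}\s+(?:design|approach|methodology|framework)'
  - id: P08
    name: we used a design
    pattern: '\bwe\s+(?:used|employed|adopted|applied)\s+(?:a|an)\s+{gap}{design}\s+(?:design|approach|methodology)'
    window: 2
  - id: P09
    name: in this design study
    pattern: '\bin\s+this\s+{design}\s+(?:study|trial|survey|analysis)'
  - id: P10
    name: this design study examined
    pattern: '\bthis\s+{design}\s+(?:study|trial|survey|review)\s+(?:examined|investigated|assessed|evaluated|aimed|compared|explored|measured|analysed|analyzed)'
  - id: P11
    name: data drawn from a design
    pattern: '\bdata\s+(?:were|was)\s+(?:drawn|collected|obtained|analysed|analyzed)\s+from\s+(?:a|an|the)\s+{gap}{design}'
    window: 3
  - id: P12
    name: we analysed data from a design
    pattern: '\bwe\s+analy[sz]ed\s+data\s+from\s+(?:a|an|the)\s+{gap}{design}'
    window: 3
  - id: P13
    name: structured design label
    pattern: '\b(?:study\s+design|design)\s*:\s*(?:a|an|the)?\s*{design}'
  - id: P14
    name: participants enrolled in a design
    pattern: '\bparticipants\s+were\s+(?:recruited|enrolled|randomi[sz]ed)\s+(?:in|into|to|for)\s+(?:a|an|this|the)\s+{gap}{design}'
    window: 3
  - id: P15
    name: as part of a design
    pattern: '\bas\s+part\s+of\s+(?:a|an|the)\s+{gap}{design}'
    window: 4
  - id: P16
    name: results of this design
    pattern: '\b(?:results|findings)\s+(?:of|from)\s+(?:this|our|a|an|the)\s+{gap}{design}'
    window: 3
  - id: P17
    name: our design study
    pattern: '\bour\s+{design}\s+(?:study\s+design|study|trial|survey|design)'
  - id: P18
    name: a design of
    pattern: '\b(?:a|an)\s+{design}(?:\s+(?:study|trial|review|survey|analysis))?\s+of\b'
  - id: P19
    name: evaluated in a design
    pattern: '\b(?:was|were)\s+(?:evaluated|assessed|examined|investigated|tested)\s+in\s+(?:a|an|this)\s+{gap}{design}'
    window: 3
  - id: P20
    name: copula design study
    pattern: '\b(?:is|was)\s+(?:a|an)\s+{gap}{design}\s+(?:study|trial|survey|review|design)\b'
    window: 2

negative:
  - id: N01
    name: follow-up of a prior design
    pattern: '\bfollow[\s-]*up\s+of\s+(?:a|an|the)\s+{gap}{design}'
    window: 2
  - id: N02
    name: following a prior analysis
    pattern: '\bfollowing\s+(?:a|an|the)\s+{gap}{design}'
    window: 2
  - id: N03
    name: protocol for a future design
    pattern: '\bprotocol\s+for\s+(?:a|an|the)?\s*(?:future|planned|forthcoming)?\s*{gap}{design}'
    window: 2
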