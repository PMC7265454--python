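# Scenario file schema

Scenario banks are YAML documents (JSON, being a YAML subset, also parses).
The top level is a mapping with a single `scenarios` list; each entry is one
avatar scenario:

```yaml
scenarios:
- id: av-4-f-abuse-1          # unique string
  age: 4                      # 4 or 6
  gender: female              # female | male
  abused: true
  background: "Narrative shown to the interviewer before the interview."
  relevant_details:           # exactly 9, indices 1..9 without gaps
  - index: 1
    category: relevant
    text: "Something happened after the activity ended"
    conclusion_critical: false
  # ... indices 6-9 must carry conclusion_critical: true
  neutral_details:            # exactly 9, indices 1..9, never critical
  - index: 1
    category: neutral
    text: "They talked happily about a red bicycle"
    conclusion_critical: false
  side_bank:                  # keyword -> ordered answer list (non-empty)
    grandfather:
    - "About grandfather: side answer 1"
    - "About grandfather: side answer 2"
  outcome:                    # ground-truth conclusion slots
    who: "her grandfather"    # all three non-empty when abused: true
    where: "in the garden shed"
    what: "touched them under their clothes"
```

Validation rules (reported all at once, with field names):

- `age` in {4, 6}; `gender` in {female, male};
- exactly 9 relevant and 9 neutral details, indices 1..9 without gaps;
- `conclusion_critical` is true exactly on relevant details 6–9;
- side-bank keywords unique after case-folding and trimming; answer lists
  non-empty (answers are served strictly in list order);
- an abused scenario must fill all three outcome slots.

`avatarlab make-scenarios --seed N --out DIR` writes the default 16-scenario
factorial bank (two scenarios per age x gender x abuse cell) in this format.
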