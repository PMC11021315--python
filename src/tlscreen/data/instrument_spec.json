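{
  "name": "TLS",
  "description": "Telephone Language Screener: nine language subtasks summed into a 0-68 total, plus an extra Backward Digit Span task excluded from the total.",
  "subtests": [
    {"name": "informative_units", "n_items": 11, "max_score": 11, "included_in_total": true},
    {"name": "spelling", "n_items": 10, "max_score": 10, "included_in_total": true},
    {"name": "semantic_association", "n_items": 6, "max_score": 6, "included_in_total": true},
    {"name": "naming_nouns", "n_items": 6, "max_score": 6, "included_in_total": true},
    {"name": "naming_verbs", "n_items": 6, "max_score": 6, "included_in_total": true},
    {"name": "cml", "n_items": 6, "max_score": 15, "included_in_total": true},
    {"name": "repetition_words", "n_items": 6, "max_score": 6, "included_in_total": true},
    {"name": "repetition_nonwords", "n_items": 5, "max_score": 5, "included_in_total": true},
    {"name": "repetition_sentences", "n_items": 3, "max_score": 3, "included_in_total": true},
    {"name": "bds_total", "n_items": 8, "max_score": 8, "included_in_total": false},
    {"name": "bds_wm", "n_items": 8, "max_score": 6, "included_in_total": false}
  ],
  "cml_item_maxima": [3, 2, 3, 2, 3, 2],
  "bds_sequence_lengths": [2, 2, 3, 3, 4, 4, 5, 6],
  "tbcli_item_groups": [1, 1, 4, 1]
}
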