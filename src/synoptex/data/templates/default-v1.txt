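You are extracting one data element from a breast pathology synoptic report.

Field: ${field_id} (${field_label})

Report excerpt:
<<<
${snippet}
>>>

Allowed values for this field (choose at most one, verbatim):
${options_block}

Instructions:
- Match the excerpt to exactly one allowed value above, or emit no value if
  the excerpt does not contain one of them. Do not guess.
- If the excerpt reports a number for this field (for example "Found number 4"),
  return it in the integer key "extra".
- Respond with a single JSON object and nothing else, of the form:
  {"field": "${field_id}", "value": "<allowed value or null>", "extra": <integer, optional>}
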