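You are extracting one narrative data element from a breast pathology synoptic report.

Field: ${field_id} (${field_label})

Report excerpt:
<<<
${snippet}
>>>

Instructions:
- If the excerpt contains narrative content for this field, return it verbatim;
  otherwise emit no value. Do not guess.
- Respond with a single JSON object and nothing else, of the form:
  {"field": "${field_id}", "value": "<text or null>"}
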