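section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
comments,Comment,comment,Comment,free_text,,,
comments,Comment,comment_pathologist,Pathologist comment,free_text,,,
comments,Clinical correlation,clinical_correlation,Clinical correlation,free_text,,,
comments,Clinical correlation,clinical_correlation_needed,Clinical correlation recommended,categorical,No|Yes,,
comments,Addendum,addendum,Addendum,free_text,,,
comments,Addendum,addendum_reason,Addendum reason,categorical,Additional findings reported|Amended diagnosis|Clerical correction|Other (specify),,
comments,Gross description note,gross_note,Gross description note,free_text,,,
comments,Gross description note,gross_ink_colors,Ink color designations,free_text,,,
comments,Gross description note,frozen_section_note,Frozen section note,free_text,,,
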