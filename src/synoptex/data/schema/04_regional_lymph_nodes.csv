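section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
regional lymph nodes,Number of lymph nodes examined,ln_examined,Number examined,numeric_template,Number examined: —,Number examined: —,
regional lymph nodes,Number of lymph nodes examined,ln_total_positive,Total with metastases,numeric_template,Total with metastases: —,Total with metastases: —,
regional lymph nodes,Number of lymph nodes examined,ln_examined_note,Nodes examined note,free_text,,,
regional lymph nodes,Number of sentinel nodes examined,ln_sentinel_examined,Sentinel nodes examined,numeric_template,Number of sentinel nodes: —,Number of sentinel nodes: —,
regional lymph nodes,Number of sentinel nodes examined,ln_sentinel_positive,Sentinel nodes with metastases,numeric_template,Sentinel nodes positive: —,Sentinel nodes positive: —,
regional lymph nodes,Number of sentinel nodes examined,ln_sentinel_note,Sentinel node note,free_text,,,
regional lymph nodes,Number with macrometastases,ln_macro,Nodes with macrometastases,numeric_template,Number: — nodes,Number: — nodes,
regional lymph nodes,Number with macrometastases,ln_macro_note,Macrometastasis note,free_text,,,
regional lymph nodes,Number with micrometastases,ln_micro,Nodes with micrometastases,numeric_template,Number: — nodes,Number: — nodes,
regional lymph nodes,Number with micrometastases,ln_micro_note,Micrometastasis note,free_text,,,
regional lymph nodes,Number with isolated tumor cells,ln_itc,Nodes with isolated tumor cells,numeric_template,Number: — nodes,Number: — nodes,
regional lymph nodes,Number with isolated tumor cells,ln_itc_note,Isolated tumor cells note,free_text,,,
regional lymph nodes,Size of largest metastatic deposit,ln_largest_met,Size of largest deposit,numeric_template,Size of largest deposit: — mm,Size of largest deposit: — mm,
regional lymph nodes,Size of largest metastatic deposit,ln_largest_met_node,Node bearing largest deposit,categorical,Sentinel node|Non-sentinel node,,
regional lymph nodes,Size of largest metastatic deposit,ln_largest_met_note,Largest deposit note,free_text,,,
regional lymph nodes,Extranodal extension,ene,Extranodal extension,categorical,Not identified|Present|Cannot be determined,,
regional lymph nodes,Extranodal extension,ene_extent,ENE extent,numeric_template,Extent: — mm,Extent: — mm,
regional lymph nodes,Extranodal extension,ene_note,Extranodal extension note,free_text,,,
regional lymph nodes,Method of evaluation,ln_method,Method of evaluation,categorical,Hematoxylin and eosin|Immunohistochemistry|Other (specify),,Hematoxylin and eosin=>H&E
regional lymph nodes,Method of evaluation,ln_method_other,"Method, other (specify)",free_text,,,
regional lymph nodes,Method of evaluation,ln_method_levels,Levels examined,numeric_template,Levels examined: —,Levels examined: —,
regional lymph nodes,Intramammary lymph nodes,intramammary_ln,Intramammary lymph nodes,categorical,Not identified|Present,,
regional lymph nodes,Intramammary lymph nodes,intramammary_ln_count,Intramammary node count,numeric_template,Intramammary nodes: —,Intramammary nodes: —,
regional lymph nodes,Intramammary lymph nodes,intramammary_ln_note,Intramammary node note,free_text,,,
regional lymph nodes,Treatment effect in lymph nodes,ln_treatment_effect,Nodal treatment effect,categorical,No known presurgical therapy|No definite response|Probable or definite response,,
regional lymph nodes,Treatment effect in lymph nodes,ln_treatment_effect_note,Nodal treatment effect note,free_text,,,
regional lymph nodes,Regional node status,ln_status,Regional node status,categorical,Negative|Positive|Cannot be determined,,
regional lymph nodes,Regional node status,ln_status_note,Node status note,free_text,,,
regional lymph nodes,Regional node status,ln_ratio_note,Node ratio note,free_text,,,
regional lymph nodes,Lymph node comment,ln_comment,Lymph node comment,free_text,,,
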