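section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
distant metastasis,Distant site(s) involved,distant_sites,Distant site(s) involved,categorical,Non-regional lymph node(s)|Bone|Liver|Lung|Brain|Other (specify),,
distant metastasis,Distant site(s) involved,distant_sites_other,"Distant site, other (specify)",free_text,,,
distant metastasis,Distant site(s) involved,distant_sites_note,Distant site note,free_text,,,
distant metastasis,Distant site(s) involved,distant_sites_count,Number of sites involved,numeric_template,Sites involved: —,Sites involved: —,
distant metastasis,Histologic confirmation,distant_confirmed,Histologic confirmation,categorical,Confirmed histologically|Based on clinical or radiographic findings,,
distant metastasis,Histologic confirmation,distant_confirmed_note,Confirmation note,free_text,,,
distant metastasis,Distant metastasis size,distant_met_size,Greatest dimension of metastasis,numeric_template,Greatest dimension: — mm,Greatest dimension: — mm,
distant metastasis,Distant metastasis size,distant_met_size_note,Metastasis size note,free_text,,,
distant metastasis,Distant metastasis comment,distant_comment,Distant metastasis comment,free_text,,,
distant metastasis,Distant metastasis comment,distant_workup,Metastatic workup,categorical,Imaging performed|Biopsy performed|Not performed,,
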