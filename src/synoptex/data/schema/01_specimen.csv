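section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
specimen,Procedure,procedure,Procedure,categorical,Core needle biopsy|Excision without wire-guided localization|Excision with wire-guided localization|Partial mastectomy|Total mastectomy|Other (specify),,Total mastectomy=>Simple mastectomy
specimen,Procedure,procedure_other,"Procedure, other (specify)",free_text,,,
specimen,Specimen laterality,laterality,Specimen laterality,categorical,Right|Left|Not specified,,
specimen,Specimen identification,specimen_id_note,Specimen identification note,free_text,,,
specimen,Specimen identification,specimen_labeled_with,Specimen labeled with,categorical,Patient name|Medical record number|Accession number|Other (specify),,
specimen,Specimen integrity,specimen_integrity,Specimen integrity,categorical,Intact|Fragmented|Other (specify),,
specimen,Specimen integrity,specimen_integrity_other,"Specimen integrity, other (specify)",free_text,,,
specimen,Specimen size,spec_size_greatest,Greatest dimension,numeric_template,Greatest dimension: — cm,Greatest dimension: — cm,
specimen,Specimen size,spec_size_addl_x,Additional dimension (second),numeric_template,Second dimension: — cm,Second dimension: — cm,
specimen,Specimen size,spec_size_addl_y,Additional dimension (third),numeric_template,Third dimension: — cm,Third dimension: — cm,
specimen,Specimen weight,spec_weight,Specimen weight,numeric_template,Weight of specimen: — g,Weight of specimen: — g,
specimen,Specimen weight,spec_weight_note,Specimen weight note,free_text,,,
specimen,Lymph node sampling,ln_sampling,Lymph node sampling,categorical,No lymph nodes submitted|Sentinel lymph node(s)|Axillary dissection|Lymph nodes present within the breast specimen,,
specimen,Lymph node sampling,ln_sampling_other,"Lymph node sampling, other (specify)",free_text,,,
specimen,Fixative type,fixative,Fixative type,categorical,10% neutral buffered formalin|Other (specify),,
specimen,Fixative type,fixative_other,"Fixative, other (specify)",free_text,,,
specimen,Cold ischemia time,cold_ischemia,Cold ischemia duration,numeric_template,Duration: — minutes,Duration: — minutes,
specimen,Cold ischemia time,cold_ischemia_note,Cold ischemia note,free_text,,,
specimen,Time in fixative,fixation_time,Fixation duration,numeric_template,Duration: — hours,Duration: — hours,
specimen,Time in fixative,fixation_time_note,Fixation note,free_text,,,
specimen,Prior treatment,prior_treatment,Prior treatment,categorical,No known presurgical therapy|Chemotherapy|Radiation therapy|Hormonal therapy|Other (specify),,
specimen,Prior treatment,prior_treatment_other,"Prior treatment, other (specify)",free_text,,,
specimen,Prior treatment,prior_treatment_note,Prior treatment note,free_text,,,
specimen,Clinical history,clinical_history,Clinical history,free_text,,,
specimen,Clinical history,clinical_history_source,Clinical history source,categorical,Requisition form|Electronic medical record|Other (specify),,
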