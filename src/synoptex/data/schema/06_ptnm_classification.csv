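section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
pTNM classification,TNM descriptors,tnm_descriptors,TNM descriptors,categorical,Not applicable|m (multiple primary tumors)|r (recurrent)|y (posttreatment),,
pTNM classification,TNM descriptors,tnm_descriptors_note,Descriptor note,free_text,,,
pTNM classification,Primary tumor pT,pt_category,pT category,categorical,pTX|pT0|pTis (DCIS)|pTis (Paget)|pT1mi|pT1a|pT1b|pT1c|pT2|pT3|pT4a|pT4b|pT4c|pT4d,,
pTNM classification,Primary tumor pT,pt_note,pT note,free_text,,,
pTNM classification,Primary tumor pT,pt_size_basis,pT size basis,categorical,Gross measurement|Microscopic measurement|Imaging,,
pTNM classification,Regional lymph nodes pN,pn_category,pN category,categorical,pNX|pN0|pN0(i+)|pN0(mol+)|pN1mi|pN1a|pN1b|pN1c|pN2a|pN2b|pN3a|pN3b|pN3c,,
pTNM classification,Regional lymph nodes pN,pn_note,pN note,free_text,,,
pTNM classification,Regional lymph nodes pN,pn_sn_suffix,Sentinel node suffix,categorical,Not applicable|(sn),,
pTNM classification,Regional lymph nodes pN,pn_f_suffix,FNA/core suffix,categorical,Not applicable|(f),,
pTNM classification,Distant metastasis pM,pm_category,pM category,categorical,Not applicable|cM0(i+)|cM1|pM1,,
pTNM classification,Distant metastasis pM,pm_note,pM note,free_text,,,
pTNM classification,Anatomic stage group,stage_group,Stage group,categorical,Stage 0|Stage IA|Stage IB|Stage IIA|Stage IIB|Stage IIIA|Stage IIIB|Stage IIIC|Stage IV,,
pTNM classification,Anatomic stage group,stage_group_note,Stage group note,free_text,,,
pTNM classification,TNM edition,tnm_edition,TNM edition,categorical,AJCC 8th edition|Other (specify),,
pTNM classification,TNM edition,tnm_edition_other,"Edition, other (specify)",free_text,,,
pTNM classification,Posttreatment response,yp_response,Posttreatment (yp) response,categorical,Complete response|Partial response|No response|Not applicable,,
pTNM classification,Posttreatment response,yp_note,yp note,free_text,,,
pTNM classification,Residual tumor classification,r_classification,Residual tumor (R),categorical,RX|R0|R1|R2,,
pTNM classification,Residual tumor classification,r_note,R classification note,free_text,,,
pTNM classification,pTNM comment,tnm_comment,pTNM comment,free_text,,,
pTNM classification,Staging parameters,staging_multifocal,Multifocal staging basis,categorical,Not applicable|Based on largest focus,,
pTNM classification,Staging parameters,staging_note,Staging note,free_text,,,
pTNM classification,Staging parameters,staging_tumor_size,Size used for pT,numeric_template,Size used for pT: — mm,Size used for pT: — mm,
pTNM classification,Staging parameters,staging_node_count,Nodes used for pN,numeric_template,Nodes used for pN: —,Nodes used for pN: —,
pTNM classification,Staging parameters,staging_dcis_extent,DCIS extent used,numeric_template,DCIS extent used: — mm,DCIS extent used: — mm,
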