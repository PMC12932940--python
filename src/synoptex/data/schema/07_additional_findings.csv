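section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
additional findings,Additional findings,adh,Epithelial proliferative lesion,categorical,Atypical ductal hyperplasia|Atypical lobular hyperplasia|Flat epithelial atypia|Usual ductal hyperplasia|Columnar cell change|None identified,,Atypical ductal hyperplasia=>ADH|Atypical lobular hyperplasia=>ALH
additional findings,Additional findings,adh_note,Additional findings note,free_text,,,
additional findings,Microcalcifications,microcalc,Microcalcifications,categorical,Not identified|Present in DCIS|Present in invasive carcinoma|Present in benign tissue,,
additional findings,Microcalcifications,microcalc_note,Microcalcification note,free_text,,,
additional findings,Microcalcifications,microcalc_correlation,Imaging correlation,categorical,Correlates with imaging|Does not correlate|Not applicable,,
additional findings,Biopsy site changes,biopsy_site,Biopsy site changes,categorical,Not identified|Present,,
additional findings,Biopsy site changes,biopsy_site_note,Biopsy site note,free_text,,,
additional findings,Fibrocystic changes,fibrocystic,Fibrocystic changes,categorical,Not identified|Present,,
additional findings,Fibrocystic changes,fibrocystic_note,Fibrocystic note,free_text,,,
additional findings,Radial scar,radial_scar,Radial scar,categorical,Not identified|Present,,
additional findings,Radial scar,radial_scar_size,Radial scar size,numeric_template,Greatest dimension: — mm,Greatest dimension: — mm,
additional findings,Intraductal papilloma,papilloma,Intraductal papilloma,categorical,Not identified|Present|Present with atypia,,
additional findings,Intraductal papilloma,papilloma_note,Papilloma note,free_text,,,
additional findings,Pseudoangiomatous stromal hyperplasia,pash,PASH,categorical,Not identified|Present,,
additional findings,Pseudoangiomatous stromal hyperplasia,pash_note,PASH note,free_text,,,
additional findings,Other findings,other_findings,Other findings,free_text,,,
additional findings,Other findings,flat_epithelial_atypia,Flat epithelial atypia (isolated),categorical,Not identified|Present,,
additional findings,Other findings,sclerosing_adenosis,Sclerosing adenosis,categorical,Not identified|Present,,
additional findings,Other findings,duct_ectasia,Duct ectasia,categorical,Not identified|Present,,
additional findings,Other findings,fat_necrosis,Fat necrosis,categorical,Not identified|Present,,
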