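section,subsection,field_id,label,value_kind,options,numeric_template,synonyms
tumor,Tumor site,tumor_site,Tumor site,categorical,Upper outer quadrant|Lower outer quadrant|Upper inner quadrant|Lower inner quadrant|Central|Nipple|Other (specify),,Upper outer quadrant=>UOQ|Lower outer quadrant=>LOQ
tumor,Tumor site,tumor_site_other,"Tumor site, other (specify)",free_text,,,
tumor,Tumor position,tumor_position,Clock position,categorical,1 o'clock|2 o'clock|3 o'clock|4 o'clock|5 o'clock|6 o'clock|7 o'clock|8 o'clock|9 o'clock|10 o'clock|11 o'clock|12 o'clock,,
tumor,Tumor position,tumor_position_int,Distance from nipple,numeric_template,Distance from nipple: — cm,Distance from nipple: — cm,
tumor,Tumor position,tumor_position_note,Tumor position note,free_text,,,
tumor,Tumor focality,focality,Tumor focality,categorical,Single focus|Multiple foci|Cannot be determined,,
tumor,Tumor focality,focality_number,Number of foci,numeric_template,Number of foci: —,Number of foci: —,
tumor,Tumor focality,focality_note,Focality note,free_text,,,
tumor,Tumor size,tumor_size_greatest,Greatest dimension of largest focus,numeric_template,Greatest dimension of largest focus: — mm,Greatest dimension of largest focus: — mm,
tumor,Tumor size,tumor_size_addl_x,Additional dimension (second),numeric_template,Second dimension: — mm,Second dimension: — mm,
tumor,Tumor size,tumor_size_addl_y,Additional dimension (third),numeric_template,Third dimension: — mm,Third dimension: — mm,
tumor,Tumor size,tumor_size_method,Size determined by,categorical,Gross measurement|Microscopic measurement|Imaging|Other (specify),,
tumor,Histologic type,histologic_type,Histologic type,categorical,Invasive ductal carcinoma|Invasive lobular carcinoma|Invasive carcinoma with ductal and lobular features|Mucinous carcinoma|Tubular carcinoma|Medullary carcinoma|Metaplastic carcinoma|Other (specify),,Invasive ductal carcinoma=>IDC;Infiltrating ductal carcinoma|Invasive lobular carcinoma=>ILC;Infiltrating lobular carcinoma
tumor,Histologic type,histologic_type_other,"Histologic type, other (specify)",free_text,,,
tumor,Histologic type,histologic_type_note,Histologic type note,free_text,,,
tumor,Glandular differentiation,glandular_diff,Glandular (acinar) differentiation score,categorical,Score 1|Score 2|Score 3|Cannot be determined,,
tumor,Glandular differentiation,glandular_diff_note,Glandular differentiation note,free_text,,,
tumor,Nuclear pleomorphism,nuclear_pleomorphism,Nuclear pleomorphism score,categorical,Score 1|Score 2|Score 3|Cannot be determined,,
tumor,Nuclear pleomorphism,nuclear_pleomorphism_note,Nuclear pleomorphism note,free_text,,,
tumor,Mitotic rate,mitotic_rate,Mitotic rate score,categorical,Score 1|Score 2|Score 3|Cannot be determined,,
tumor,Mitotic rate,mitotic_count,Mitotic count,numeric_template,Mitotic count: — per 10 HPF,Mitotic count: — per 10 HPF,
tumor,Mitotic rate,mitotic_rate_note,Mitotic rate note,free_text,,,
tumor,Overall histologic grade,overall_grade,Overall grade (Nottingham),categorical,Grade 1|Grade 2|Grade 3|Cannot be determined,,
tumor,Overall histologic grade,grade_note,Grade note,free_text,,,
tumor,Ductal carcinoma in situ,dcis_present,DCIS,categorical,"Not identified|Present|Present, extensive intraductal component",,
tumor,Ductal carcinoma in situ,dcis_size,Estimated size (extent) of DCIS,numeric_template,Estimated size (extent) of DCIS: — mm,Estimated size (extent) of DCIS: — mm,
tumor,Ductal carcinoma in situ,dcis_blocks,Number of blocks with DCIS,numeric_template,Number of blocks with DCIS: —,Number of blocks with DCIS: —,
tumor,Ductal carcinoma in situ,dcis_blocks_examined,Number of blocks examined,numeric_template,Number of blocks examined: —,Number of blocks examined: —,
tumor,DCIS architectural patterns,dcis_pattern,Architectural patterns,categorical,Comedo|Cribriform|Micropapillary|Papillary|Solid|Other (specify),,
tumor,DCIS architectural patterns,dcis_pattern_other,"Architectural pattern, other (specify)",free_text,,,
tumor,DCIS nuclear grade,dcis_nuclear_grade,DCIS nuclear grade,categorical,Grade I (low)|Grade II (intermediate)|Grade III (high),,
tumor,DCIS nuclear grade,dcis_nuclear_grade_note,DCIS nuclear grade note,free_text,,,
tumor,DCIS necrosis,dcis_necrosis,Necrosis,categorical,"Not identified|Present, focal|Present, central (expansile)",,
tumor,DCIS necrosis,dcis_necrosis_note,Necrosis note,free_text,,,
tumor,Lobular carcinoma in situ,lcis,LCIS,categorical,Not identified|Present,,
tumor,Lobular carcinoma in situ,lcis_type,LCIS type,categorical,Classic|Pleomorphic|Florid,,
tumor,Lymphovascular invasion,lvi,Lymphovascular invasion,categorical,Not identified|Present|Cannot be determined,,Present=>LVI present
tumor,Lymphovascular invasion,lvi_extent,LVI extent,categorical,Focal|Extensive,,
tumor,Lymphovascular invasion,lvi_note,LVI note,free_text,,,
tumor,Dermal lymphatic invasion,dermal_lvi,Dermal lymphatic invasion,categorical,Not identified|Present,,
tumor,Dermal lymphatic invasion,dermal_lvi_note,Dermal lymphatic invasion note,free_text,,,
tumor,Skin involvement,skin_involvement,Skin involvement,categorical,Not identified|Invades dermis without ulceration|Invades dermis with ulceration|Satellite skin foci,,
tumor,Skin involvement,skin_note,Skin involvement note,free_text,,,
tumor,Nipple involvement,nipple_involvement,Nipple involvement,categorical,Not identified|DCIS involving nipple skin (Paget disease)|Invasive carcinoma involving nipple,,
tumor,Nipple involvement,nipple_note,Nipple involvement note,free_text,,,
tumor,Skeletal muscle involvement,muscle_involvement,Skeletal muscle involvement,categorical,Not identified|Present,,
tumor,Skeletal muscle involvement,muscle_note,Skeletal muscle note,free_text,,,
tumor,Treatment effect,treatment_effect,Treatment effect,categorical,No known presurgical therapy|No definite response|Probable or definite response|Complete response,,
tumor,Treatment effect,treatment_effect_percent,Residual tumor cellularity,numeric_template,Residual cellularity: — %,Residual cellularity: — %,
tumor,Treatment effect,treatment_effect_note,Treatment effect note,free_text,,,
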