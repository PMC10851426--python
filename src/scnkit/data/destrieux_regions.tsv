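region_id	hemisphere
lh_G_and_S_frontomargin	left
lh_G_and_S_occipital_inf	left
lh_G_and_S_paracentral	left
lh_G_and_S_subcentral	left
lh_G_and_S_transv_frontopol	left
lh_G_and_S_cingul-Ant	left
lh_G_and_S_cingul-Mid-Ant	left
lh_G_and_S_cingul-Mid-Post	left
lh_G_cingul-Post-dorsal	left
lh_G_cingul-Post-ventral	left
lh_G_cuneus	left
lh_G_front_inf-Opercular	left
lh_G_front_inf-Orbital	left
lh_G_front_inf-Triangul	left
lh_G_front_middle	left
lh_G_front_sup	left
lh_G_Ins_lg_and_S_cent_ins	left
lh_G_insular_short	left
lh_G_occipital_middle	left
lh_G_occipital_sup	left
lh_G_oc-temp_lat-fusifor	left
lh_G_oc-temp_med-Lingual	left
lh_G_oc-temp_med-Parahip	left
lh_G_orbital	left
lh_G_pariet_inf-Angular	left
lh_G_pariet_inf-Supramar	left
lh_G_parietal_sup	left
lh_G_postcentral	left
lh_G_precentral	left
lh_G_precuneus	left
lh_G_rectus	left
lh_G_subcallosal	left
lh_G_temp_sup-G_T_transv	left
lh_G_temp_sup-Lateral	left
lh_G_temp_sup-Plan_polar	left
lh_G_temp_sup-Plan_tempo	left
lh_G_temporal_inf	left
lh_G_temporal_middle	left
lh_Lat_Fis-ant-Horizont	left
lh_Lat_Fis-ant-Vertical	left
lh_Lat_Fis-post	left
lh_Pole_occipital	left
lh_Pole_temporal	left
lh_S_calcarine	left
lh_S_central	left
lh_S_cingul-Marginalis	left
lh_S_circular_insula_ant	left
lh_S_circular_insula_inf	left
lh_S_circular_insula_sup	left
lh_S_collat_transv_ant	left
lh_S_collat_transv_post	left
lh_S_front_inf	left
lh_S_front_middle	left
lh_S_front_sup	left
lh_S_interm_prim-Jensen	left
lh_S_intrapariet_and_P_trans	left
lh_S_oc_middle_and_Lunatus	left
lh_S_oc_sup_and_transversal	left
lh_S_occipital_ant	left
lh_S_oc-temp_lat	left
lh_S_oc-temp_med_and_Lingual	left
lh_S_orbital_lateral	left
lh_S_orbital_med-olfact	left
lh_S_orbital-H_Shaped	left
lh_S_parieto_occipital	left
lh_S_pericallosal	left
lh_S_postcentral	left
lh_S_precentral-inf-part	left
lh_S_precentral-sup-part	left
lh_S_suborbital	left
lh_S_subparietal	left
lh_S_temporal_inf	left
lh_S_temporal_sup	left
lh_S_temporal_transverse	left
rh_G_and_S_frontomargin	right
rh_G_and_S_occipital_inf	right
rh_G_and_S_paracentral	right
rh_G_and_S_subcentral	right
rh_G_and_S_transv_frontopol	right
rh_G_and_S_cingul-Ant	right
rh_G_and_S_cingul-Mid-Ant	right
rh_G_and_S_cingul-Mid-Post	right
rh_G_cingul-Post-dorsal	right
rh_G_cingul-Post-ventral	right
rh_G_cuneus	right
rh_G_front_inf-Opercular	right
rh_G_front_inf-Orbital	right
rh_G_front_inf-Triangul	right
rh_G_front_middle	right
rh_G_front_sup	right
rh_G_Ins_lg_and_S_cent_ins	right
rh_G_insular_short	right
rh_G_occipital_middle	right
rh_G_occipital_sup	right
rh_G_oc-temp_lat-fusifor	right
rh_G_oc-temp_med-Lingual	right
rh_G_oc-temp_med-Parahip	right
rh_G_orbital	right
rh_G_pariet_inf-Angular	right
rh_G_pariet_inf-Supramar	right
rh_G_parietal_sup	right
rh_G_postcentral	right
rh_G_precentral	right
rh_G_precuneus	right
rh_G_rectus	right
rh_G_subcallosal	right
rh_G_temp_sup-G_T_transv	right
rh_G_temp_sup-Lateral	right
rh_G_temp_sup-Plan_polar	right
rh_G_temp_sup-Plan_tempo	right
rh_G_temporal_inf	right
rh_G_temporal_middle	right
rh_Lat_Fis-ant-Horizont	right
rh_Lat_Fis-ant-Vertical	right
rh_Lat_Fis-post	right
rh_Pole_occipital	right
rh_Pole_temporal	right
rh_S_calcarine	right
rh_S_central	right
rh_S_cingul-Marginalis	right
rh_S_circular_insula_ant	right
rh_S_circular_insula_inf	right
rh_S_circular_insula_sup	right
rh_S_collat_transv_ant	right
rh_S_collat_transv_post	right
rh_S_front_inf	right
rh_S_front_middle	right
rh_S_front_sup	right
rh_S_interm_prim-Jensen	right
rh_S_intrapariet_and_P_trans	right
rh_S_oc_middle_and_Lunatus	right
rh_S_oc_sup_and_transversal	right
rh_S_occipital_ant	right
rh_S_oc-temp_lat	right
rh_S_oc-temp_med_and_Lingual	right
rh_S_orbital_lateral	right
rh_S_orbital_med-olfact	right
rh_S_orbital-H_Shaped	right
rh_S_parieto_occipital	right
rh_S_pericallosal	right
rh_S_postcentral	right
rh_S_precentral-inf-part	right
rh_S_precentral-sup-part	right
rh_S_suborbital	right
rh_S_subparietal	right
rh_S_temporal_inf	right
rh_S_temporal_sup	right
rh_S_temporal_transverse	right
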