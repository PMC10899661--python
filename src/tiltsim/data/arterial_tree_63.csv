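name,parent,bed,length_cm,r_prox_mm,r_dist_mm,c0_m_s,dz_m
aortic_root,-,,2.0,14.7,14.5,4.8,0.02
ascending_aorta,aortic_root,,3.0,14.5,13.8,4.8,0.03
aortic_arch_1,ascending_aorta,,2.0,13.2,12.8,5.0,0.01
aortic_arch_2,aortic_arch_1,,3.0,12.7,12.4,5.0,0.0
aortic_arch_3,aortic_arch_2,,3.9,12.3,12.0,5.1,-0.005
thoracic_aorta_1,aortic_arch_3,,5.2,11.2,10.5,5.2,-0.05
thoracic_aorta_2,thoracic_aorta_1,,10.4,10.0,8.5,5.4,-0.1
abdominal_aorta_1,thoracic_aorta_2,,5.3,7.9,7.5,5.6,-0.05
abdominal_aorta_2,abdominal_aorta_1,,4.3,7.3,7.1,5.7,-0.04
abdominal_aorta_3,abdominal_aorta_2,,2.0,7.0,6.9,5.8,-0.02
abdominal_aorta_4,abdominal_aorta_3,,2.0,6.8,6.7,5.8,-0.02
abdominal_aorta_5,abdominal_aorta_4,,2.0,6.6,6.5,5.9,-0.02
abdominal_aorta_6,abdominal_aorta_5,,5.3,6.3,5.9,6.0,-0.05
brachiocephalic,aortic_arch_1,,3.4,6.3,6.1,5.6,0.0
r_common_carotid_1,brachiocephalic,,8.5,3.9,3.8,6.2,0.07
r_common_carotid_2,r_common_carotid_1,,8.5,3.8,3.7,6.4,0.07
l_common_carotid_1,aortic_arch_2,,10.0,3.9,3.8,6.2,0.07
l_common_carotid_2,l_common_carotid_1,,10.0,3.8,3.7,6.4,0.07
r_internal_carotid_1,r_common_carotid_2,,13.0,2.6,2.4,7.2,0.12
r_internal_carotid_2,r_internal_carotid_1,cerebral_ica_r,4.7,2.2,2.0,7.6,0.025
l_internal_carotid_1,l_common_carotid_2,,13.0,2.6,2.4,7.2,0.12
l_internal_carotid_2,l_internal_carotid_1,cerebral_ica_l,4.7,2.2,2.0,7.6,0.025
r_external_carotid,r_common_carotid_2,head_ec,10.0,1.9,1.5,7.8,0.1
l_external_carotid,l_common_carotid_2,head_ec,10.0,1.9,1.5,7.8,0.1
r_vertebral,r_subclavian,cerebral_vert,14.8,1.4,1.3,8.5,0.24
l_vertebral,l_subclavian,cerebral_vert,14.8,1.4,1.3,8.5,0.24
r_subclavian,brachiocephalic,,3.4,4.2,4.0,6.0,0.02
l_subclavian,aortic_arch_3,,3.4,4.2,4.0,6.0,0.02
r_axillary,r_subclavian,,6.1,3.6,3.3,6.6,-0.06
l_axillary,l_subclavian,,6.1,3.6,3.3,6.6,-0.06
r_brachial,r_axillary,,22.0,3.2,2.8,7.0,-0.2
l_brachial,l_axillary,,22.0,3.2,2.8,7.0,-0.2
r_radial,r_brachial,arms,23.0,1.6,1.4,8.8,-0.23
l_radial,l_brachial,arms,23.0,1.6,1.4,8.8,-0.23
r_ulnar_1,r_brachial,,6.7,2.2,2.1,8.0,-0.06
l_ulnar_1,l_brachial,,6.7,2.2,2.1,8.0,-0.06
r_ulnar_2,r_ulnar_1,arms,17.0,2.0,1.8,8.4,-0.17
l_ulnar_2,l_ulnar_1,arms,17.0,2.0,1.8,8.4,-0.17
celiac,abdominal_aorta_1,,2.0,3.9,3.7,6.4,-0.01
splenic,celiac,upper_abd,6.3,2.8,2.6,7.0,-0.02
hepatic,celiac,upper_abd,6.6,2.2,2.1,7.4,-0.02
superior_mesenteric,abdominal_aorta_2,upper_abd,5.9,4.3,4.1,6.2,-0.03
l_renal,abdominal_aorta_3,upper_abd,3.2,2.6,2.5,7.0,-0.02
r_renal,abdominal_aorta_4,upper_abd,3.2,2.6,2.5,7.0,-0.02
inferior_mesenteric,abdominal_aorta_5,lower_abd,5.0,1.6,1.5,8.0,-0.03
r_common_iliac,abdominal_aorta_6,,5.8,3.7,3.5,6.6,-0.058
l_common_iliac,abdominal_aorta_6,,5.8,3.7,3.5,6.6,-0.058
r_external_iliac,r_common_iliac,,14.4,3.2,2.9,7.0,-0.14
l_external_iliac,l_common_iliac,,14.4,3.2,2.9,7.0,-0.14
r_internal_iliac,r_common_iliac,lower_abd,5.0,2.0,1.9,7.8,-0.05
l_internal_iliac,l_common_iliac,lower_abd,5.0,2.0,1.9,7.8,-0.05
r_femoral,r_external_iliac,,26.0,2.6,2.3,7.6,-0.255
l_femoral,l_external_iliac,,26.0,2.6,2.3,7.6,-0.255
r_deep_femoral,r_femoral,legs,12.6,2.0,1.8,8.2,-0.12
l_deep_femoral,l_femoral,legs,12.6,2.0,1.8,8.2,-0.12
r_popliteal,r_femoral,,18.5,2.2,2.0,8.0,-0.18
l_popliteal,l_femoral,,18.5,2.2,2.0,8.0,-0.18
r_anterior_tibial,r_popliteal,legs,34.0,1.1,1.0,9.6,-0.33
l_anterior_tibial,l_popliteal,legs,34.0,1.1,1.0,9.6,-0.33
r_posterior_tibial,r_popliteal,legs,32.0,1.1,1.0,9.6,-0.31
l_posterior_tibial,l_popliteal,legs,32.0,1.1,1.0,9.6,-0.31
l_coronary,aortic_root,coronary,1.0,2.1,2.0,7.6,0.005
r_coronary,ascending_aorta,coronary,1.0,1.7,1.6,8.0,0.005
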