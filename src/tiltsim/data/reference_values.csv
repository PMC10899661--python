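name,channel,kind,units,pre,post,location
aortic MAP,p_ao,mean,mmHg,92.8,86.1,Results: cerebrovascular steady-state comparison
ICA left mean pressure,p_ica_l,mean,mmHg,65.8,87.2,Results: cerebrovascular steady-state comparison
MCA left mean pressure,p_mca_l,mean,mmHg,63.4,84.5,Results: proximal-to-distal mean increments
distal MCA left mean pressure,p_dm_l,mean,mmHg,36.5,52.7,Results: proximal-to-distal mean increments
cerebral capillary mean pressure,p_ccap,mean,mmHg,14.4,26.4,Results: proximal-to-distal mean increments
cerebral venous mean pressure,p_cv,mean,mmHg,4.16,15.46,Results: proximal-to-distal mean increments
dural sinus mean pressure,p_dvs,mean,mmHg,-10.8,9.0,Results: dural sinus outflow discussion
superior vena cava mean pressure,p_svc,mean,mmHg,-0.5,7.9,Results: dural sinus outflow discussion
central venous pressure,p_ra,mean,mmHg,2.1,7.6,Results: dural sinus outflow discussion
cerebral blood flow,cbf,mean,ml/s,11.63,12.4,Results: CBF autoregulation plateau
intracranial pressure,icp,mean,mmHg,-0.1,10.9,Results: ocular-cephalic responses
intraocular pressure,iop,mean,mmHg,15.8,19.9,Results: ocular-cephalic responses
translaminar pressure,tlp,mean,mmHg,15.9,9.0,Results: ocular-cephalic responses
ocular perfusion pressure,opp,mean,mmHg,49.6,65.1,Results: ocular-cephalic responses
eye arterial pressure,pa_eye,mean,mmHg,65.4,85.0,Results: eye-level pressures
eye venous pressure,pv_eye,mean,mmHg,2.1,7.6,Results: eye-level pressures
pulse ICP,icp,pulse,mmHg,0.01,1.7,Results: pulsatile responses
pulse IOP,iop,pulse,mmHg,6.9,8.7,Results: pulsatile responses
pulse TLP,tlp,pulse,mmHg,6.9,8.4,Results: pulsatile responses
pulse OPP,opp,pulse,mmHg,47.8,57.5,Results: pulsatile responses
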