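key,background_rstar,value,sem,n,units,note
psp_ssi,0.5,0.07,0.01,13,,surround suppression index of AII PSP size-tuning curves
psp_ssi,500,0.19,0.01,13,,surround suppression index of AII PSP size-tuning curves
psp_ssi,25000,0.29,0.01,12,,surround suppression index of AII PSP size-tuning curves
nbqx_charge_reduction_pct,0.5,97.7,1.4,6,%,EPSC charge reduction by NBQX for an 88 um spot
nbqx_charge_reduction_pct,500,89.8,2.9,6,%,EPSC charge reduction by NBQX for an 88 um spot
nbqx_charge_reduction_pct,25000,7.7,12.3,6,%,EPSC charge reduction by NBQX for an 88 um spot
rf_center_um,0.5,100.9,13.6,13,um,smallest spot producing maximal depolarization
rf_center_um,500,96.4,9.4,13,um,reference only; single sigma_c fitted to the scotopic value
rf_center_um,25000,92.4,7.1,12,um,reference only; single sigma_c fitted to the scotopic value
peak_dv_88um_mv,0.5,3.7,0.8,13,mV,peak depolarization to an 88 um spot
peak_dv_88um_mv,500,10.9,1.4,13,mV,peak depolarization to an 88 um spot
peak_dv_88um_mv,25000,12.0,,,mV,assumed: photopic small-spot PSPs comparable to mesopic
epsc_peak_88um_pa,0.5,30,,,pA,assumed EPSC amplitude scale
epsc_peak_88um_pa,500,60,,,pA,assumed EPSC amplitude scale
epsc_peak_88um_pa,25000,55,,,pA,assumed EPSC amplitude scale
epsc_ssi_control,0.5,0.08,0.02,6,,EPSC charge SSI without drugs
epsc_ssi_control,500,0.34,0.04,8,,EPSC charge SSI without drugs
epsc_ssi_control,25000,0.41,0.03,10,,EPSC charge SSI without drugs
epsc_ssi_ttx,0.5,0.07,0.01,6,,EPSC charge SSI with TTX
epsc_ssi_ttx,500,0.15,0.02,8,,EPSC charge SSI with TTX
epsc_ssi_ttx,25000,0.17,0.01,10,,EPSC charge SSI with TTX
epsc_ssi_ttx_hepes,500,0.04,0.02,5,,reference only; model surround fully removed
epsc_ssi_ttx_hepes,25000,0.04,0.01,6,,reference only; model surround fully removed
annulus_transient_mv,0.5,0.0,,10,mV,no surround-only response at the scotopic background
annulus_transient_mv,500,-3.3,0.9,10,mV,transient hyperpolarization to a +100% annulus
annulus_transient_mv,25000,-4.5,0.8,10,mV,transient hyperpolarization to a +100% annulus
rgc_spike_ssi,25000,0.35,0.04,5,,s-ONalpha spike-count SSI (WT)
rgc_spike_ssi_cx36ko,25000,0.04,0.02,5,,reference only; surround removed in the knockout
ipsc_charge_1200um_pc,0.5,13.6,6.5,8,pC,TTX-sensitive IPSC charge for a 1200 um spot
ipsc_charge_1200um_pc,500,22.5,4.2,8,pC,TTX-sensitive IPSC charge for a 1200 um spot
ipsc_charge_1200um_pc,25000,21.5,5.7,8,pC,TTX-sensitive IPSC charge for a 1200 um spot
glycine_peak_charge_pc,25000,7.8,2.0,5,pC,narrow-field glycinergic IPSC charge at 88 um
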