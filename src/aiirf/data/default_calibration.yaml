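sigma_c_um: 16.5
sigma_s_um: 300.0
sigma_c_rgc_um: 45.0
sigma_gly_c_um: 40.0
sigma_gly_s_um: 70.0
tau_on_s: 0.04
tau_off_s: 0.04
tau_sus_s: 0.06
tau_trans_s: 0.09
trans_delay_s: 0.06
noise_sd_mv: 0.3
noise_sd_pa: 2.0
noise_bw_hz: 100.0
cell_cv: 0.3
trial_cv: 0.05
gabazine_boost: 1.3
rate_base_hz: 4.0
rate_gain_hz: 160.0
w_post_spk: 0.4
clip_mv: 40.0
clip_pa: 600.0
backgrounds:
  '0.5':
    a_center_mv: 3.8161603854955835
    a_epsc_pa: 30.949025876197457
    a_ipsc_pa: 39.97670853850816
    f_rbc: 0.977
    f_transient: 0.2262010917517061
    w_pre_psp: 0.2264105979339392
    w_pre_epsc: 0.2537225966570655
    w_pre_spk: 0.09773596320188531
    w_post_mv: 0.0
    glycine_gain_pa: 0.0
  '500':
    a_center_mv: 11.275437724330606
    a_epsc_pa: 62.20734313480682
    a_ipsc_pa: 95.78715854303553
    f_rbc: 0.898
    f_transient: 0.8164772125060248
    w_pre_psp: 1.2615058048305323
    w_pre_epsc: 2.526349436695915
    w_pre_spk: 0.9731699061623162
    w_post_mv: 5.017713027100506
    glycine_gain_pa: 0.0
  '25000':
    a_center_mv: 12.500863435590212
    a_epsc_pa: 57.13919652376991
    a_ipsc_pa: 94.41038932600729
    f_rbc: 0.077
    f_transient: 0.8566499363258476
    w_pre_psp: 4.312160169976627
    w_pre_epsc: 3.7593039960629078
    w_pre_spk: 1.4481138135304241
    w_post_mv: 6.820420560189445
    glycine_gain_pa: 61.72214340339798
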