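target_id,precursor_mz,rt_center,rt_window,charge
withanoside_iv,800.4427,3.2,1.0,1
withanoside_v,784.4478,3.9,1.0,1
withaferin_a,471.2741,4.6,1.0,1
deoxywithastramonolide,471.2741,5.1,1.0,1
withanolide_a,471.2741,5.6,1.0,1
withanone,471.2741,6.1,1.0,1
withanolide_b,455.2792,6.8,1.0,1
digoxin_d3,784.4557,7.4,1.0,1
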