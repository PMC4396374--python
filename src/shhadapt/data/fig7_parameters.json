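{
  "tl_Ptc": 100,
  "tl_X": 1,
  "tl_GliFL": 100,
  "conv_GliR": 0.01,
  "tr_gliFL": 100,
  "tr_x": 1,
  "deg_ptc": 2,
  "tr_ptc": 100,
  "Pol": 1,
  "deg_Ptc": 0.1,
  "deg_GliFL": 0.1,
  "deg_GliA": 1.5,
  "deg_GliR": 0.01,
  "deg_X": 0.5,
  "deg_x": 1,
  "K_Gli_ptc": 1,
  "deg_gliFL": 0.03,
  "conv_GliA": 10,
  "K_X_gli": 10,
  "K_Pol_ptc": 1,
  "K_Pol_x": 1,
  "K_Pol_gli": 0.01,
  "c_GliA": 10,
  "c_GliR": 0,
  "k_ShhPtc": 100,
  "Km_Ptch1": 1,
  "K_Gli_x": 10,
  "act_Ptc": 10,
  "c_X": 0
}
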