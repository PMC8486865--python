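# Medication first (ThermoDox + hyperthermia), thermal ablation of the
# center at the end of the window -- the ordering the study recommends.
protocol:
  protocol: medication_then_ablation
  agent: thermodox
  dose: 50.0
  hyperthermia_window: [0.0, 3600.0]
  ablation_window: [86340.0, 60.0]
  total_sim_time: 86400.0
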