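# 60 s focused-ultrasound ablation of the tumor center, then ThermoDox
# therapy starting immediately (switch agent to free_dox for
# ablation + thermochemotherapy).
protocol:
  protocol: ablation_then_medication
  agent: thermodox
  dose: 50.0
  ablation_window: [0.0, 60.0]
  hyperthermia_window: [70.0, 3600.0]
  total_sim_time: 86400.0
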