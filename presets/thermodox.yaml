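# ThermoDox therapy: thermosensitive-liposome bolus + 1 h mild hyperthermia
# triggering intravascular release in the tumor microvessels.
protocol:
  protocol: thermodox
  agent: thermodox
  dose: 50.0
  hyperthermia_window: [0.0, 3600.0]
  total_sim_time: 86400.0
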