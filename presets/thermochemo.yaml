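# Thermochemotherapy: free doxorubicin + 1 h nanoparticle mild hyperthermia.
protocol:
  protocol: thermochemo
  agent: free_dox
  dose: 50.0
  hyperthermia_window: [0.0, 3600.0]
  total_sim_time: 86400.0
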