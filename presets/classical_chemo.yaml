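# Classical chemotherapy: free doxorubicin bolus, no heating.
# Dose in mg/m^2 (50/100/150 are the study's permissible doses).
protocol:
  protocol: classical_chemo
  agent: free_dox
  dose: 50.0
  total_sim_time: 86400.0
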