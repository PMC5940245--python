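{
  "comment": "Steady-state and time-constant sigmoid parameters for the voltage-gated variables of the single-compartment neuron. x_inf(V) = 1/(1+exp((V-v_half)/v_slope)); tau_x(V) = A - B/(1+exp((V-D)/E)). h_Na uses a dedicated tau formula and carries no A/B/D/E entries.",
  "m_Na":  {"v_half": -35.5, "v_slope": -5.29, "A": 1.32,  "B": 1.26,   "D": -120.0, "E": -25.0},
  "h_Na":  {"v_half": -48.9, "v_slope": 5.18,  "A": null,  "B": null,   "D": null,   "E": null},
  "m_Kd":  {"v_half": -12.3, "v_slope": -11.8, "A": 7.2,   "B": 6.4,    "D": -28.3,  "E": -19.2},
  "m_CaT": {"v_half": -67.1, "v_slope": -7.2,  "A": 21.7,  "B": 21.3,   "D": -68.1,  "E": -20.5},
  "h_CaT": {"v_half": -80.1, "v_slope": 5.5,   "A": 410.0, "B": 179.6,  "D": -55.0,  "E": -16.9},
  "m_H":   {"v_half": -80.0, "v_slope": 6.0,   "A": 272.0, "B": -1149.0,"D": -42.2,  "E": -8.73}
}
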