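{
  "description": "Frozen reference constants of the surrogate electro-mechanical cardiomyocyte model. The eleven scalable parameters (gNa ... kom) are given at their reference (all-ones) values; the remaining entries are fixed model constants tuned once so the reference model satisfies every packaged calibration range.",
  "units": {
    "voltage": "mV",
    "time": "ms",
    "calcium": "uM",
    "conductances": "mV/ms per unit driving force (membrane capacitance normalized to 1)",
    "length": "fraction of L_max (L_max = sarcomere length 2.23 um)",
    "force": "arbitrary model units; reported forces are divided by reference_peak_force"
  },
  "parameters": {
    "gNa": 4.0,
    "gCaL": 0.13,
    "gK1": 1.5,
    "gKs": 0.015,
    "gKr": 0.032,
    "Vmaxup": 0.65,
    "KNaCa": 0.1,
    "PNaK": 1.0,
    "ks": 0.0006,
    "kim": 0.005,
    "kom": 0.06,
    "gNab": 0.02,
    "kcal": 0.015,
    "kleak": 8e-06,
    "vsr_ratio": 15.0,
    "kact": 0.3,
    "kact_half": 1.0,
    "ec50_sr": 1500.0,
    "ki_ca": 0.01,
    "Btot": 70.0,
    "a_on": 0.015,
    "a_off": 0.022,
    "alpha_xb": 2.0,
    "kp_xb": 0.004,
    "km_xb": 0.003,
    "B_half": 30.0,
    "n_hill": 3.0,
    "v0": 0.004,
    "f_scale": 1.0,
    "c_pas": 0.002,
    "s_pas": 10.0,
    "cv_detach": 2.0,
    "overlap_zero": 0.6,
    "fca_half": 0.8,
    "K_up": 0.25,
    "CaSR_init": 3000.0,
    "reference_peak_force": 0.2731556707104622,
    "k_bgca": 0.022,
    "diastolic_threshold": 56.0
  }
}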