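{
  "scenario": "scenario_one",
  "seed": 1,
  "reps": 200,
  "n_grid": [50, 80, 100, 200, 500, 1000]
}
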