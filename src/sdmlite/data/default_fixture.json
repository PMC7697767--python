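{
  "nrows": 60,
  "ncols": 100,
  "n_layers": 6,
  "length_scale": 2.0,
  "correlation": 0.15,
  "n_presences": 400,
  "mode": "probabilistic",
  "seed": 20201111,
  "x0": -25.0,
  "y0": 15.0,
  "cellsize": 0.5,
  "ocean": [[0, 18], [70, 100]],
  "used_variables": ["bio1", "bio4"],
  "optima": [13.0, 850.0],
  "breadths": [1.0, 60.0]
}
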