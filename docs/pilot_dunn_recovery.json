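{
  "description": "pilot Monte-Carlo recovery of persistent-random-walk speed/persistence from per-fragment MSD fits",
  "grid": [
    {
      "S_true": 0.1,
      "P_true": 20.0,
      "S_hat_mean": 0.1037,
      "P_hat_mean": 19.869,
      "S_rel_err": 0.037,
      "P_rel_err": 0.0066,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.1,
      "P_true": 40.0,
      "S_hat_mean": 0.10128,
      "P_hat_mean": 39.371,
      "S_rel_err": 0.0128,
      "P_rel_err": 0.0157,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.1,
      "P_true": 80.0,
      "S_hat_mean": 0.10007,
      "P_hat_mean": 81.969,
      "S_rel_err": 0.0007,
      "P_rel_err": 0.0246,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.15,
      "P_true": 20.0,
      "S_hat_mean": 0.15639,
      "P_hat_mean": 19.637,
      "S_rel_err": 0.0426,
      "P_rel_err": 0.0181,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.15,
      "P_true": 40.0,
      "S_hat_mean": 0.15365,
      "P_hat_mean": 41.292,
      "S_rel_err": 0.0243,
      "P_rel_err": 0.0323,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.15,
      "P_true": 80.0,
      "S_hat_mean": 0.15111,
      "P_hat_mean": 82.209,
      "S_rel_err": 0.0074,
      "P_rel_err": 0.0276,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.2,
      "P_true": 20.0,
      "S_hat_mean": 0.20472,
      "P_hat_mean": 21.34,
      "S_rel_err": 0.0236,
      "P_rel_err": 0.067,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.2,
      "P_true": 40.0,
      "S_hat_mean": 0.20208,
      "P_hat_mean": 41.882,
      "S_rel_err": 0.0104,
      "P_rel_err": 0.047,
      "n_fragments": 200,
      "n_frames": 450
    },
    {
      "S_true": 0.2,
      "P_true": 80.0,
      "S_hat_mean": 0.20317,
      "P_hat_mean": 83.854,
      "S_rel_err": 0.0159,
      "P_rel_err": 0.0482,
      "n_fragments": 200,
      "n_frames": 450
    }
  ],
  "max_S_rel_err": 0.0426,
  "max_P_rel_err": 0.067
}
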