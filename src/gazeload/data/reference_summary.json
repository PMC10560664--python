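{
  "description": "Published reference group x condition summary statistics (mean, sd) for the three gaze metrics, used for arithmetic-consistency checks of pooled means and load effects.",
  "groups": ["control", "manic", "depression"],
  "conditions": ["no_load", "high_load"],
  "cells": {
    "aoi_sample_pct": {
      "control": {"no_load": [65.50, 9.75], "high_load": [70.56, 7.90]},
      "manic": {"no_load": [65.86, 9.52], "high_load": [73.38, 8.62]},
      "depression": {"no_load": [57.38, 6.35], "high_load": [64.29, 5.91]}
    },
    "aoi_fixation_duration_s": {
      "control": {"no_load": [389.2, 59.50], "high_load": [420.2, 50.0]},
      "manic": {"no_load": [394.0, 53.85], "high_load": [436.8, 47.49]},
      "depression": {"no_load": [344.5, 38.6], "high_load": [386.0, 32.0]}
    },
    "fixation_distribution": {
      "control": {"no_load": [0.107, 0.018], "high_load": [0.096, 0.020]},
      "manic": {"no_load": [0.105, 0.021], "high_load": [0.089, 0.021]},
      "depression": {"no_load": [0.097, 0.015], "high_load": [0.083, 0.020]}
    }
  }
}
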