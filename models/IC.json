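{
  "model_id": "IC",
  "notes": "",
  "nodes": [
    {
      "label": "MGB_L",
      "region": "MGB",
      "hemisphere": "L",
      "depth_class": "deep",
      "is_input": true
    },
    {
      "label": "A1_L",
      "region": "A1",
      "hemisphere": "L",
      "depth_class": "superficial",
      "is_input": false
    },
    {
      "label": "IC_L",
      "region": "IC",
      "hemisphere": "L",
      "depth_class": "deep",
      "is_input": false
    },
    {
      "label": "MGB_R",
      "region": "MGB",
      "hemisphere": "R",
      "depth_class": "deep",
      "is_input": true
    },
    {
      "label": "A1_R",
      "region": "A1",
      "hemisphere": "R",
      "depth_class": "superficial",
      "is_input": false
    },
    {
      "label": "IC_R",
      "region": "IC",
      "hemisphere": "R",
      "depth_class": "deep",
      "is_input": false
    }
  ],
  "connections": [
    {
      "source_label": "MGB_L",
      "target_label": "A1_L",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "A1_L",
      "target_label": "IC_L",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "MGB_L",
      "target_label": "IC_L",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 8.0
    },
    {
      "source_label": "A1_L",
      "target_label": "MGB_L",
      "ctype": "backward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "IC_L",
      "target_label": "A1_L",
      "ctype": "backward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "MGB_R",
      "target_label": "A1_R",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "A1_R",
      "target_label": "IC_R",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "MGB_R",
      "target_label": "IC_R",
      "ctype": "forward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 8.0
    },
    {
      "source_label": "A1_R",
      "target_label": "MGB_R",
      "ctype": "backward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    },
    {
      "source_label": "IC_R",
      "target_label": "A1_R",
      "ctype": "backward",
      "prior_log_gain_mean": 0.0,
      "prior_log_gain_variance": 0.0625,
      "delay_ms": 16.0
    }
  ]
}
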