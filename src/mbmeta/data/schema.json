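{
  "format": "UTF-8 comma-separated values, header row mandatory, empty string or '-' = missing",
  "columns": {
    "study_id": {"type": "text", "description": "Source study (first author + year)"},
    "figure_panel": {"type": "text", "description": "Figure panel the data were extracted from"},
    "genotype_exp": {"type": "text", "description": "Experimental-arm genotype"},
    "genotype_ctrl": {"type": "text", "description": "Control-arm genotype (same genotype at permissive temperature for shibire/heat records)"},
    "n_exp": {"type": "integer", "min": 1, "description": "Experimental-arm iterations (restrictive-temperature iterations for shibire/heat records)"},
    "n_ctrl": {"type": "integer", "min": 1, "description": "Control-arm iterations (permissive-temperature iterations for shibire/heat records)"},
    "pi_exp_mean": {"type": "number", "range": [-1, 1], "nullable": true, "description": "Mean Performance Index, experimental arm"},
    "pi_exp_sem": {"type": "number", "min": 0, "nullable": true, "description": "SEM of the experimental-arm PI"},
    "pi_ctrl_mean": {"type": "number", "range": [-1, 1], "nullable": true, "description": "Mean Performance Index, control arm"},
    "pi_ctrl_sem": {"type": "number", "min": 0, "nullable": true, "description": "SEM of the control-arm PI"},
    "intervention": {"type": "enum", "values": ["rut_rescue", "rut_mutant", "shi_inactivation", "heat_control"]},
    "lobe_category": {"type": "enum", "values": ["alphabeta", "alphaprime_betaprime", "gamma", "alphabeta_gamma", "all_lobes", "none"], "description": "'none' only for rut_mutant and heat_control records"},
    "driver": {"type": "text", "nullable": true, "description": "Transgenic driver line; '+' joins multi-driver combinations"},
    "odor_pair": {"type": "text", "description": "Conditioning odor pair abbreviation (e.g. MCH-BEN)"},
    "benzaldehyde": {"type": "boolean", "description": "True iff the odor pair names benzaldehyde (BEN)"},
    "temperature_c": {"type": "number", "nullable": true, "description": "Experimental temperature in Celsius; printed ranges collapse to midpoints"},
    "shock_v": {"type": "number", "nullable": true, "description": "Conditioning shock in volts"},
    "current_type": {"type": "enum", "values": ["AC", "DC", "unknown"]},
    "delay_min": {"type": "number", "min": 0, "description": "Training-to-test delay in minutes; 'immediately' codes as 0"},
    "rh_pct": {"type": "number", "nullable": true, "description": "Relative humidity percent; ranges collapse to midpoints"},
    "shared_control_id": {"type": "text", "nullable": true, "description": "Records sharing one control arm carry the same id"}
  }
}
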