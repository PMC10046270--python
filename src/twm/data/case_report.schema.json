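{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CaseReport",
  "type": "object",
  "required": ["case_id", "burden", "etiology", "exposures", "cnv", "msi_status"],
  "properties": {
    "case_id": {"type": "string"},
    "burden": {
      "type": "object",
      "required": [
        "total_mutations", "pathogenic_per_exome", "wgs_tmb_per_mb",
        "panel_tmb_equiv", "tmb_high"
      ],
      "properties": {
        "total_mutations": {"type": "integer", "minimum": 0},
        "pathogenic_per_exome": {"type": "integer", "minimum": 0},
        "wgs_tmb_per_mb": {"type": "number", "minimum": 0},
        "panel_tmb_equiv": {"type": "number", "minimum": 0},
        "tmb_high": {"type": "boolean"}
      }
    },
    "etiology": {
      "type": "object",
      "required": ["uv_share", "uv_band", "apobec_flag", "hrd_band"],
      "properties": {
        "uv_share": {"type": "number", "minimum": 0, "maximum": 1},
        "uv_band": {"type": "string", "enum": ["predominant", "minor"]},
        "apobec_flag": {"type": "boolean"},
        "hrd_band": {"type": "string", "enum": ["none", "minor", "present"]}
      }
    },
    "exposures": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "cnv": {
      "type": "object",
      "required": [
        "n_total", "n_amplification", "n_trisomy_gain", "n_homozygous_loss",
        "n_loh", "loh_percent", "hrd_loh_score", "hrd_high"
      ],
      "properties": {
        "n_total": {"type": "integer", "minimum": 0},
        "n_amplification": {"type": "integer", "minimum": 0},
        "n_trisomy_gain": {"type": "integer", "minimum": 0},
        "n_homozygous_loss": {"type": "integer", "minimum": 0},
        "n_loh": {"type": "integer", "minimum": 0},
        "loh_percent": {"type": "number", "minimum": 0, "maximum": 100},
        "hrd_loh_score": {"type": "integer", "minimum": 0},
        "hrd_high": {"type": "boolean"}
      }
    },
    "msi_status": {"type": "string", "enum": ["MSS", "MSI", "unknown"]},
    "n_catalog": {"type": "integer", "minimum": 0},
    "n_skipped_no_context": {"type": "integer", "minimum": 0}
  }
}
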