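{
 "$defs": {
  "EmulatorConfig": {
   "properties": {
    "preset": {
     "default": "default",
     "enum": [
      "default",
      "apoe850_mimic"
     ],
     "title": "Preset",
     "type": "string"
    },
    "noise_sd": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Noise Sd"
    },
    "period": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Period"
    },
    "w_sat": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "W Sat"
    },
    "lambda_start": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Lambda Start"
    },
    "lambda_end": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Lambda End"
    }
   },
   "title": "EmulatorConfig",
   "type": "object"
  },
  "GenomeSpecConfig": {
   "properties": {
    "n_genes": {
     "default": 2,
     "title": "N Genes",
     "type": "integer"
    },
    "gene_length_range": {
     "default": [
      3000,
      6000
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "integer"
      },
      {
       "type": "integer"
      }
     ],
     "title": "Gene Length Range",
     "type": "array"
    },
    "exon_count_range": {
     "default": [
      3,
      6
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "integer"
      },
      {
       "type": "integer"
      }
     ],
     "title": "Exon Count Range",
     "type": "array"
    },
    "exon_length_range": {
     "default": [
      100,
      400
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "integer"
      },
      {
       "type": "integer"
      }
     ],
     "title": "Exon Length Range",
     "type": "array"
    },
    "intergenic_length_range": {
     "default": [
      4000,
      8000
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "integer"
      },
      {
       "type": "integer"
      }
     ],
     "title": "Intergenic Length Range",
     "type": "array"
    },
    "gc_content": {
     "default": 0.41,
     "title": "Gc Content",
     "type": "number"
    },
    "chrom_name": {
     "default": "chrS",
     "title": "Chrom Name",
     "type": "string"
    }
   },
   "title": "GenomeSpecConfig",
   "type": "object"
  },
  "RunConfig": {
   "description": "Everything a run needs; fully JSON-serializable.",
   "properties": {
    "seed": {
     "default": 0,
     "title": "Seed",
     "type": "integer"
    },
    "outdir": {
     "default": "ntprobe_out",
     "title": "Outdir",
     "type": "string"
    },
    "genome": {
     "$ref": "#/$defs/GenomeSpecConfig",
     "default": {
      "n_genes": 2,
      "gene_length_range": [
       3000,
       6000
      ],
      "exon_count_range": [
       3,
       6
      ],
      "exon_length_range": [
       100,
       400
      ],
      "intergenic_length_range": [
       4000,
       8000
      ],
      "gc_content": 0.41,
      "chrom_name": "chrS"
     }
    },
    "emulator": {
     "$ref": "#/$defs/EmulatorConfig",
     "default": {
      "preset": "default",
      "noise_sd": null,
      "period": null,
      "w_sat": null,
      "lambda_start": null,
      "lambda_end": null
     }
    },
    "n_min": {
     "default": 2,
     "title": "N Min",
     "type": "integer"
    },
    "n_max": {
     "default": 7,
     "title": "N Max",
     "type": "integer"
    },
    "token_size": {
     "default": 6,
     "title": "Token Size",
     "type": "integer"
    },
    "gene": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Gene"
    },
    "validation_genes": {
     "items": {
      "type": "string"
     },
     "title": "Validation Genes",
     "type": "array"
    },
    "control_region_length": {
     "default": 2000,
     "title": "Control Region Length",
     "type": "integer"
    },
    "probe_offset": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Probe Offset"
    },
    "trace_window": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Trace Window"
    },
    "position_classes": {
     "items": {
      "type": "string"
     },
     "title": "Position Classes",
     "type": "array"
    },
    "raw_threshold": {
     "default": 0.5,
     "title": "Raw Threshold",
     "type": "number"
    },
    "normalized_threshold": {
     "default": 0.0,
     "title": "Normalized Threshold",
     "type": "number"
    },
    "epsilon_auc": {
     "default": 0.005,
     "title": "Epsilon Auc",
     "type": "number"
    },
    "trim": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Trim"
    },
    "detrend_window": {
     "default": 101,
     "title": "Detrend Window",
     "type": "integer"
    },
    "m_max": {
     "default": 48,
     "title": "M Max",
     "type": "integer"
    },
    "tau": {
     "default": 0.99,
     "title": "Tau",
     "type": "number"
    },
    "anova_period": {
     "default": 24,
     "title": "Anova Period",
     "type": "integer"
    },
    "rolling_window": {
     "default": 6,
     "title": "Rolling Window",
     "type": "integer"
    },
    "stabilization_thresholds": {
     "items": {
      "type": "number"
     },
     "title": "Stabilization Thresholds",
     "type": "array"
    }
   },
   "title": "RunConfig",
   "type": "object"
  },
  "StageRecord": {
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "seconds": {
     "title": "Seconds",
     "type": "number"
    },
    "outputs": {
     "items": {
      "type": "string"
     },
     "title": "Outputs",
     "type": "array"
    },
    "skipped": {
     "default": false,
     "title": "Skipped",
     "type": "boolean"
    },
    "note": {
     "default": "",
     "title": "Note",
     "type": "string"
    }
   },
   "required": [
    "name",
    "seconds",
    "outputs"
   ],
   "title": "StageRecord",
   "type": "object"
  }
 },
 "properties": {
  "config": {
   "$ref": "#/$defs/RunConfig"
  },
  "config_hash": {
   "title": "Config Hash",
   "type": "string"
  },
  "package_version": {
   "title": "Package Version",
   "type": "string"
  },
  "stages": {
   "items": {
    "$ref": "#/$defs/StageRecord"
   },
   "title": "Stages",
   "type": "array"
  }
 },
 "required": [
  "config",
  "config_hash",
  "package_version",
  "stages"
 ],
 "title": "AuditManifest",
 "type": "object"
}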