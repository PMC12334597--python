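{
  "$defs": {
    "ClusterAssociation": {
      "properties": {
        "table": {
          "items": {
            "items": {
              "type": "integer"
            },
            "type": "array"
          },
          "title": "Table",
          "type": "array"
        },
        "test_name": {
          "title": "Test Name",
          "type": "string"
        },
        "p_value": {
          "maximum": 1,
          "minimum": 0,
          "title": "P Value",
          "type": "number"
        }
      },
      "required": [
        "table",
        "test_name",
        "p_value"
      ],
      "title": "ClusterAssociation",
      "type": "object"
    },
    "CoxRow": {
      "properties": {
        "covariate": {
          "title": "Covariate",
          "type": "string"
        },
        "coefficient": {
          "title": "Coefficient",
          "type": "number"
        },
        "hazard_ratio": {
          "title": "Hazard Ratio",
          "type": "number"
        },
        "p_value": {
          "maximum": 1,
          "minimum": 0,
          "title": "P Value",
          "type": "number"
        }
      },
      "required": [
        "covariate",
        "coefficient",
        "hazard_ratio",
        "p_value"
      ],
      "title": "CoxRow",
      "type": "object"
    },
    "CoxSection": {
      "properties": {
        "feature": {
          "title": "Feature",
          "type": "string"
        },
        "mode": {
          "title": "Mode",
          "type": "string"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "n_events": {
          "title": "N Events",
          "type": "integer"
        },
        "rows": {
          "items": {
            "$ref": "#/$defs/CoxRow"
          },
          "title": "Rows",
          "type": "array"
        }
      },
      "required": [
        "feature",
        "mode",
        "converged",
        "n",
        "n_events",
        "rows"
      ],
      "title": "CoxSection",
      "type": "object"
    },
    "HighConfidencePair": {
      "properties": {
        "cluster_id": {
          "title": "Cluster Id",
          "type": "integer"
        },
        "gene_id": {
          "title": "Gene Id",
          "type": "string"
        },
        "microbe_id": {
          "title": "Microbe Id",
          "type": "string"
        },
        "rho": {
          "maximum": 1,
          "minimum": -1,
          "title": "Rho",
          "type": "number"
        }
      },
      "required": [
        "cluster_id",
        "gene_id",
        "microbe_id",
        "rho"
      ],
      "title": "HighConfidencePair",
      "type": "object"
    },
    "IntegrationSection": {
      "properties": {
        "k": {
          "title": "K",
          "type": "integer"
        },
        "host_only": {
          "title": "Host Only",
          "type": "integer"
        },
        "microbe_only": {
          "title": "Microbe Only",
          "type": "integer"
        },
        "heterologous": {
          "title": "Heterologous",
          "type": "integer"
        },
        "n_high_confidence": {
          "title": "N High Confidence",
          "type": "integer"
        },
        "high_confidence_pairs": {
          "items": {
            "$ref": "#/$defs/HighConfidencePair"
          },
          "title": "High Confidence Pairs",
          "type": "array"
        }
      },
      "required": [
        "k",
        "host_only",
        "microbe_only",
        "heterologous",
        "n_high_confidence",
        "high_confidence_pairs"
      ],
      "title": "IntegrationSection",
      "type": "object"
    },
    "LogrankRow": {
      "properties": {
        "stratification": {
          "title": "Stratification",
          "type": "string"
        },
        "groups": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Groups",
          "type": "object"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        },
        "p_value": {
          "maximum": 1,
          "minimum": 0,
          "title": "P Value",
          "type": "number"
        }
      },
      "required": [
        "stratification",
        "groups",
        "statistic",
        "p_value"
      ],
      "title": "LogrankRow",
      "type": "object"
    },
    "MarkerRow": {
      "properties": {
        "feature_id": {
          "title": "Feature Id",
          "type": "string"
        },
        "delta": {
          "title": "Delta",
          "type": "number"
        },
        "t_statistic": {
          "title": "T Statistic",
          "type": "number"
        },
        "p_value": {
          "maximum": 1,
          "minimum": 0,
          "title": "P Value",
          "type": "number"
        },
        "q_value": {
          "maximum": 1,
          "minimum": 0,
          "title": "Q Value",
          "type": "number"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        }
      },
      "required": [
        "feature_id",
        "delta",
        "t_statistic",
        "p_value",
        "q_value",
        "significant"
      ],
      "title": "MarkerRow",
      "type": "object"
    },
    "MdClusterSection": {
      "properties": {
        "k": {
          "title": "K",
          "type": "integer"
        },
        "labels": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Labels",
          "type": "object"
        },
        "cluster_sizes": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Cluster Sizes",
          "type": "object"
        },
        "association": {
          "anyOf": [
            {
              "$ref": "#/$defs/ClusterAssociation"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "k",
        "labels",
        "cluster_sizes"
      ],
      "title": "MdClusterSection",
      "type": "object"
    },
    "SurvivalSection": {
      "properties": {
        "logrank": {
          "items": {
            "$ref": "#/$defs/LogrankRow"
          },
          "title": "Logrank",
          "type": "array"
        },
        "cox": {
          "anyOf": [
            {
              "$ref": "#/$defs/CoxSection"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "logrank"
      ],
      "title": "SurvivalSection",
      "type": "object"
    }
  },
  "description": "Schema of report.json; class counts always sum to the integration K.",
  "properties": {
    "version": {
      "title": "Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "md_cluster": {
      "$ref": "#/$defs/MdClusterSection"
    },
    "markers": {
      "items": {
        "$ref": "#/$defs/MarkerRow"
      },
      "title": "Markers",
      "type": "array"
    },
    "integration": {
      "$ref": "#/$defs/IntegrationSection"
    },
    "survival": {
      "$ref": "#/$defs/SurvivalSection"
    }
  },
  "required": [
    "version",
    "seed",
    "config",
    "md_cluster",
    "markers",
    "integration",
    "survival"
  ],
  "title": "PipelineReport",
  "type": "object"
}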