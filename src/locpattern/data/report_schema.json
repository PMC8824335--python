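{
  "$defs": {
    "ContingencyEntry": {
      "properties": {
        "df": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Df"
        },
        "error": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Error"
        },
        "margin": {
          "title": "Margin",
          "type": "string"
        },
        "p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P"
        },
        "statistic": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Statistic"
        },
        "table": {
          "items": {
            "items": {
              "type": "integer"
            },
            "type": "array"
          },
          "title": "Table",
          "type": "array"
        }
      },
      "required": [
        "margin",
        "table"
      ],
      "title": "ContingencyEntry",
      "type": "object"
    },
    "PowerEntry": {
      "properties": {
        "alpha": {
          "title": "Alpha",
          "type": "number"
        },
        "mc_se": {
          "title": "Mc Se",
          "type": "number"
        },
        "n1": {
          "title": "N1",
          "type": "integer"
        },
        "n2": {
          "title": "N2",
          "type": "integer"
        },
        "n_sims": {
          "title": "N Sims",
          "type": "integer"
        },
        "p1": {
          "title": "P1",
          "type": "number"
        },
        "p2": {
          "title": "P2",
          "type": "number"
        },
        "power": {
          "title": "Power",
          "type": "number"
        }
      },
      "required": [
        "p1",
        "n1",
        "p2",
        "n2",
        "alpha",
        "n_sims",
        "power",
        "mc_se"
      ],
      "title": "PowerEntry",
      "type": "object"
    },
    "RegressionEntry": {
      "properties": {
        "model_stats": {
          "additionalProperties": true,
          "title": "Model Stats",
          "type": "object"
        },
        "terms": {
          "items": {
            "$ref": "#/$defs/TermEntry"
          },
          "title": "Terms",
          "type": "array"
        }
      },
      "required": [
        "terms",
        "model_stats"
      ],
      "title": "RegressionEntry",
      "type": "object"
    },
    "TermEntry": {
      "properties": {
        "df": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Df"
        },
        "estimate": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Estimate"
        },
        "p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "P"
        },
        "se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Se"
        },
        "t": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "T"
        },
        "term": {
          "title": "Term",
          "type": "string"
        }
      },
      "required": [
        "term",
        "estimate",
        "se",
        "df",
        "t",
        "p"
      ],
      "title": "TermEntry",
      "type": "object"
    }
  },
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "contingency": {
      "items": {
        "$ref": "#/$defs/ContingencyEntry"
      },
      "title": "Contingency",
      "type": "array"
    },
    "correlations": {
      "additionalProperties": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Correlations",
      "type": "object"
    },
    "errors": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Errors",
      "type": "array"
    },
    "n_subjects": {
      "title": "N Subjects",
      "type": "integer"
    },
    "power": {
      "anyOf": [
        {
          "$ref": "#/$defs/PowerEntry"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "regressions": {
      "additionalProperties": {
        "$ref": "#/$defs/RegressionEntry"
      },
      "title": "Regressions",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    }
  },
  "required": [
    "config",
    "seed",
    "n_subjects",
    "correlations",
    "regressions",
    "contingency"
  ],
  "title": "Report",
  "type": "object"
}
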