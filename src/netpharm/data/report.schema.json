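{
  "type": "object",
  "required": ["schema_version", "config_hash", "seed", "compounds", "profiles", "integration"],
  "properties": {
    "schema_version": {"type": "integer"},
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "compounds": {
      "type": "object",
      "properties": {
        "n_input": {"type": "integer"},
        "n_pass_adme": {"type": "integer"},
        "unique_compounds": {"type": "integer"},
        "total_assignments": {"type": "integer"},
        "per_herb": {"type": "object", "additionalProperties": {"type": "integer"}}
      }
    },
    "profiles": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "status": {"type": "string"},
          "deg": {
            "type": "object",
            "properties": {
              "n_genes": {"type": "integer"},
              "n_up": {"type": "integer"},
              "n_down": {"type": "integer"}
            }
          },
          "ct_network": {
            "type": "object",
            "properties": {
              "n_compounds": {"type": "integer"},
              "n_targets": {"type": "integer"},
              "n_nodes": {"type": "integer"},
              "n_edges": {"type": "integer"},
              "top_compounds": {"type": "array"}
            }
          },
          "cascade": {
            "type": "object",
            "properties": {
              "stages": {"type": "array", "items": {"type": "object"}},
              "final_nodes": {"type": "array", "items": {"type": "string"}},
              "empty_after_stage1": {"type": "boolean"}
            }
          },
          "enrichment": {
            "type": "object",
            "properties": {
              "n_tested": {"type": "integer"},
              "n_significant": {"type": "integer"},
              "top_terms": {"type": "object"}
            }
          }
        }
      }
    },
    "integration": {
      "type": "object",
      "properties": {
        "venn_targets": {"type": "object"},
        "venn_screened": {"type": "object"},
        "at_least_2": {"type": "array", "items": {"type": "string"}},
        "key_pathways": {"type": "array"},
        "gene_pathway": {"type": "object"}
      }
    },
    "recovery": {
      "type": "object",
      "properties": {
        "core_precision": {"type": "number"},
        "core_recall": {"type": "number"},
        "planted_pathway_recovered": {"type": "boolean"}
      }
    }
  }
}
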