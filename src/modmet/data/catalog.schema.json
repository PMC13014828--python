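{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "modmet module catalog (TSV dialect)",
  "description": "Tab-separated, one row per metabolic module. ko_groups: requirement groups separated by '|', alternative member KOs within a group separated by ';' (a module is present when every group has at least one member KO in the genome). substrates/products: ';'-separated compound names from the controlled vocabulary, matched case-insensitively. direction: transporters only (import / export / bidirectional); metabolic modules use 'none'.",
  "type": "object",
  "properties": {
    "module_id": {"type": "string", "pattern": "^PN?[0-9]+$"},
    "name": {"type": "string"},
    "pathway": {
      "enum": ["rTCA", "WLP", "rGly_Ser", "CBB", "3HP", "PAT_ACK",
               "dicarboxylate_hydroxybutyrate", "fermentation", "anaplerotic",
               "fatty_acid", "nitrogen", "transport"]
    },
    "ko_groups": {"type": "string", "pattern": "^K[0-9]{5}([;|]K[0-9]{5})*$"},
    "substrates": {"type": "string"},
    "products": {"type": "string"},
    "direction": {"enum": ["import", "export", "bidirectional", "none"]}
  },
  "required": ["module_id", "name", "pathway", "ko_groups", "substrates",
               "products", "direction"]
}
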