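{
  "framework": "acta-research-merit",
  "provenance": "published-mean",
  "description": "Mean stakeholder point system (percentage points) for the ACTA research-merit framework, elicited from 220 consumers, researchers and funders. Values are stored exactly as printed; the four top-level values sum to 100.1 because of rounding.",
  "values": [
    {"criterion": "Appropriateness", "level_rank": 1, "level_label": "Low", "points": 0.0},
    {"criterion": "Appropriateness", "level_rank": 2, "level_label": "Medium-low", "points": 10.2},
    {"criterion": "Appropriateness", "level_rank": 3, "level_label": "Medium", "points": 18.7},
    {"criterion": "Appropriateness", "level_rank": 4, "level_label": "Medium-high", "points": 24.7},
    {"criterion": "Appropriateness", "level_rank": 5, "level_label": "High", "points": 29.3},
    {"criterion": "Significance", "level_rank": 1, "level_label": "Low", "points": 0.0},
    {"criterion": "Significance", "level_rank": 2, "level_label": "Medium-low", "points": 9.1},
    {"criterion": "Significance", "level_rank": 3, "level_label": "Medium", "points": 16.8},
    {"criterion": "Significance", "level_rank": 4, "level_label": "Medium-high", "points": 22.3},
    {"criterion": "Significance", "level_rank": 5, "level_label": "High", "points": 26.6},
    {"criterion": "Relevance", "level_rank": 1, "level_label": "Low", "points": 0.0},
    {"criterion": "Relevance", "level_rank": 2, "level_label": "Medium-low", "points": 8.8},
    {"criterion": "Relevance", "level_rank": 3, "level_label": "Medium", "points": 16.1},
    {"criterion": "Relevance", "level_rank": 4, "level_label": "Medium-high", "points": 21.2},
    {"criterion": "Relevance", "level_rank": 5, "level_label": "High", "points": 25.0},
    {"criterion": "Feasibility", "level_rank": 1, "level_label": "Low", "points": 0.0},
    {"criterion": "Feasibility", "level_rank": 2, "level_label": "Medium-low", "points": 7.5},
    {"criterion": "Feasibility", "level_rank": 3, "level_label": "Medium", "points": 13.3},
    {"criterion": "Feasibility", "level_rank": 4, "level_label": "Medium-high", "points": 16.9},
    {"criterion": "Feasibility", "level_rank": 5, "level_label": "High", "points": 19.2}
  ]
}
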