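name: acta-research-merit
version: "1.0"
criteria:
  - name: Appropriateness
    clarification: >-
      Should the research be done? The extent to which the study design and
      study quality are appropriate to answer the research question.
    levels:
      - {label: Low, elicited: true}
      - {label: Medium-low, elicited: false}
      - {label: Medium, elicited: true}
      - {label: Medium-high, elicited: false}
      - {label: High, elicited: true}
  - name: Significance
    clarification: >-
      What does society get out of it? The extent to which society overall
      benefits or capacity, partnerships or innovation are enhanced.
    levels:
      - {label: Low, elicited: true}
      - {label: Medium-low, elicited: false}
      - {label: Medium, elicited: true}
      - {label: Medium-high, elicited: false}
      - {label: High, elicited: true}
  - name: Relevance
    clarification: >-
      Why do the research? The extent to which high-burden conditions or
      stakeholder needs are addressed.
    levels:
      - {label: Low, elicited: true}
      - {label: Medium-low, elicited: false}
      - {label: Medium, elicited: true}
      - {label: Medium-high, elicited: false}
      - {label: High, elicited: true}
  - name: Feasibility
    clarification: >-
      Can it be done? The extent to which researchers are able to deliver
      outputs on time and within budget.
    levels:
      - {label: Low, elicited: true}
      - {label: Medium-low, elicited: false}
      - {label: Medium, elicited: true}
      - {label: Medium-high, elicited: false}
      - {label: High, elicited: true}
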