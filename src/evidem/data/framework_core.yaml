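# EVIDEM core model (10th edition): 5 domains, 13 criteria.
# Absolute criteria are scored 0..5 against a fixed anchor; relative criteria
# are scored -5..5 against the comparator drug class (here, PPIs).
domains:
- id: need
  name: Need for intervention
- id: outcomes
  name: Comparative outcomes of intervention
- id: benefit
  name: Type of benefit of intervention
- id: economic
  name: Economic consequences of intervention
- id: knowledge
  name: Knowledge about intervention
criteria:
- id: disease_severity
  name: Disease severity
  domain: need
  scale: absolute
  indicators: [Morbidity, Progression, Quality of life]
- id: population_size
  name: Size of the affected population
  domain: need
  scale: absolute
  indicators: [Disease incidence]
- id: unmet_needs
  name: Unmet needs
  domain: need
  scale: absolute
  indicators: [Compliance, Response rate, Nocturnal acid breakthrough, Genetic polymorphism]
- id: comparative_effectiveness
  name: Comparative effectiveness
  domain: outcomes
  scale: relative
  indicators: [Reflux esophagitis healing rate, Intragastric pH]
- id: comparative_safety
  name: Comparative safety
  domain: outcomes
  scale: relative
  indicators: [Incidence of adverse effects]
- id: patient_perceived_health
  name: Comparative patient-perceived health
  domain: outcomes
  scale: relative
  indicators: [Heartburn]
- id: preventive_benefit
  name: Type of preventive benefit
  domain: benefit
  scale: absolute
  indicators: [Preventive benefit]
- id: therapeutic_benefit
  name: Type of therapeutic benefit
  domain: benefit
  scale: absolute
  indicators: [Therapeutic benefit]
- id: intervention_costs
  name: Comparative cost consequences - costs of intervention
  domain: economic
  scale: relative
  indicators: [Drug cost]
- id: other_medical_costs
  name: Comparative cost consequences - other medical costs
  domain: economic
  scale: relative
  indicators: [Pharmacoeconomic research in China]
- id: non_medical_costs
  name: Comparative cost consequences - non-medical costs
  domain: economic
  scale: relative
  indicators: [Pharmacoeconomic research in China]
- id: quality_of_evidence
  name: Quality of evidence
  domain: knowledge
  scale: absolute
  indicators: [Type of evidence, Level of evidence]
- id: guidelines
  name: Expert consensus / clinical practice guidelines
  domain: knowledge
  scale: absolute
  indicators: [Recommendation]
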