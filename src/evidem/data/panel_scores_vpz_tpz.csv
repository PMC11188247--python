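# Published PTC panel score summary for vonoprazan (VPZ) vs tegoprazan (TPZ)
# in GERD treatment, 14-expert panel; mean and SD on each criterion's scale.
# Zero-mean rows with no_evidence=yes carry a score of 0 because the panel
# retrieved no evidence for that criterion/intervention (SD not reported,
# stored as 0).
intervention,criterion_id,mean,sd,no_evidence
VPZ,disease_severity,2.9,0.6,no
VPZ,population_size,3.5,1.1,no
VPZ,unmet_needs,4.2,0.6,no
VPZ,comparative_effectiveness,3.9,1.1,no
VPZ,comparative_safety,3.0,0.6,no
VPZ,patient_perceived_health,2.5,1.0,no
VPZ,preventive_benefit,3.6,0.9,no
VPZ,therapeutic_benefit,4.1,0.9,no
VPZ,intervention_costs,0.9,0.7,no
VPZ,other_medical_costs,1.3,0.9,no
VPZ,non_medical_costs,0.0,0.0,yes
VPZ,quality_of_evidence,2.4,0.7,no
VPZ,guidelines,3.5,1.0,no
TPZ,disease_severity,2.9,0.6,no
TPZ,population_size,3.5,1.1,no
TPZ,unmet_needs,4.2,0.6,no
TPZ,comparative_effectiveness,3.4,1.0,no
TPZ,comparative_safety,3.1,0.5,no
TPZ,patient_perceived_health,2.4,1.2,no
TPZ,preventive_benefit,3.4,1.0,no
TPZ,therapeutic_benefit,3.8,1.1,no
TPZ,intervention_costs,-0.6,0.5,no
TPZ,other_medical_costs,0.0,0.0,yes
TPZ,non_medical_costs,0.0,0.0,yes
TPZ,quality_of_evidence,2.4,0.7,no
TPZ,guidelines,3.5,1.0,no
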