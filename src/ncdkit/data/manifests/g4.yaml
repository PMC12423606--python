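# Synthetic fixture manifest reconstructing the analyzed application G4.
app_id: G4
app_name: NutritionRush
app_type: serious game
platform: Android
risk_factor: nutrition
bct_list:
  - information-about-health-consequences
gamification_elements: [high-scores]
educational_content: true
usability_tested: true
graphics: true
audio: true
genre: platformer
intuitive_controls: true
social_features: []
availability: false
cost: free
platform_barrier: low
clinician_involved: false
interoperable_export: false
key_area_evidence: {C1: none, C2: partial, C3: none, C4: none, C5: partial, C6: partial}
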