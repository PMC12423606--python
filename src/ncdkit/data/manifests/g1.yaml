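# Synthetic fixture manifest reconstructing the analyzed application G1.
app_id: G1
app_name: BreathIn
app_type: serious game
platform: Android
risk_factor: smoking
bct_list:
  - information-about-health-consequences
  - self-monitoring-of-behavior
  - feedback-on-behavior
  - incentive-outcome
gamification_elements: [achievements]
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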