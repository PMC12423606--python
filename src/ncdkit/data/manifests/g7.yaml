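# Synthetic fixture manifest reconstructing the analyzed application G7.
app_id: G7
app_name: MoodBooster
app_type: gamified app
platform: Android
risk_factor: mental-health
bct_list:
  - information-about-health-consequences
  - self-monitoring-of-behavior
  - feedback-on-behavior
  - incentive-outcome
gamification_elements: [badges]
educational_content: true
usability_tested: true
graphics: true
audio: true
genre: tracker
intuitive_controls: true
social_features: []
availability: false
cost: free
platform_barrier: low
clinician_involved: false
interoperable_export: false
key_area_evidence: {C1: none, C2: partial, C3: none, C4: none, C5: partial, C6: partial}
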