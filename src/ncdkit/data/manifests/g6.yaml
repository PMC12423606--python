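# Synthetic fixture manifest reconstructing the analyzed application G6.
app_id: G6
app_name: recoverApp
app_type: gamified app
platform: Android and PC
risk_factor: mental-health
bct_list:
  - self-monitoring-of-behavior
  - feedback-on-behavior
  - incentive-outcome
  - social-support
  - graded-tasks
gamification_elements: [achievements, points]
educational_content: false
usability_tested: true
graphics: true
audio: false
genre: tracker
intuitive_controls: true
social_features: [chat, therapist-tasks]
availability: false
cost: free
platform_barrier: low
clinician_involved: true
interoperable_export: false
key_area_evidence: {C1: none, C2: partial, C3: none, C4: none, C5: partial, C6: partial}
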