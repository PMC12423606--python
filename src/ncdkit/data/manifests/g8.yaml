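# Synthetic fixture manifest reconstructing the analyzed application G8.
app_id: G8
app_name: DiaBeaThis
app_type: gamified web application
platform: Web (PC and mobile)
risk_factor: hyperglycemia
bct_list:
  - self-monitoring-of-behavior
  - feedback-on-behavior
  - incentive-outcome
  - social-comparison
gamification_elements: [experience-points, achievements, leaderboard]
educational_content: false
usability_tested: true
graphics: false
audio: false
genre: card-game
intuitive_controls: true
social_features: [leaderboard, versus-game]
availability: false
cost: free
platform_barrier: low
clinician_involved: false
interoperable_export: false
key_area_evidence: {C1: none, C2: partial, C3: none, C4: none, C5: partial, C6: partial}
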