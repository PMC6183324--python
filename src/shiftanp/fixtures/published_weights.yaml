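# Published group-level weights, transcribed at the printed 3-decimal
# precision. Criterion and sub-criterion weights from the per-group weight
# tables; alternative weights from the ranking paragraphs of the results.
# Values are kept exactly as printed even where a group's printed values do
# not sum to 1 (loaders attach sum-check warnings instead of failing):
# the security group's alternative weights sum to 1.26, and the support
# group's ranking omits the evening shift.
# The security table's group header misprints "second group"; entries here
# are keyed by shift pattern, not by that header.
nurses_8h:
  label: "Nurses working 8-hour shifts (3-3-3-3 rotation)"
  criteria:
    sleep_disorders: 0.297
    personal_life_disorders: 0.122
    family_life_disorders: 0.113
    mental_disorders: 0.275
    digestive_disorders: 0.137
    cardiovascular_disorders: 0.032
    musculoskeletal_disorders: 0.024
  subcriteria:
    sleep_disorders: {sleeplessness: 0.633, hypnotics: 0.366}
    personal_life_disorders: {rest: 0.634, exercise: 0.365}
    family_life_disorders: {household_chores: 0.745, children_parents: 0.146, family_ceremonies: 0.108}
    mental_disorders: {headache_dizziness: 0.052, anger: 0.194, impatience: 0.133, depression: 0.619}
    digestive_disorders: {appetite_change: 0.273, constipation: 0.104, ulcers: 0.621}
    cardiovascular_disorders: {dyspnea: 0.600, high_blood_pressure: 0.082, low_blood_pressure: 0.317}
    musculoskeletal_disorders: {sore_neck: 0.089, backache: 0.632, sore_leg_knee: 0.278}
  alternatives:
    night_shift: 0.656
    evening_shift: 0.183
    morning_shift: 0.160
support_12_24:
  label: "Support personnel working 12-24 hour shift patterns"
  criteria:
    sleep_disorders: 0.252
    personal_life_disorders: 0.167
    family_life_disorders: 0.120
    mental_disorders: 0.164
    digestive_disorders: 0.198
    cardiovascular_disorders: 0.067
    musculoskeletal_disorders: 0.033
  subcriteria:
    sleep_disorders: {sleeplessness: 0.546, hypnotics: 0.454}
    personal_life_disorders: {rest: 0.567, exercise: 0.433}
    family_life_disorders: {household_chores: 0.672, children_parents: 0.116, family_ceremonies: 0.212}
    mental_disorders: {headache_dizziness: 0.095, anger: 0.236, impatience: 0.147, depression: 0.522}
    digestive_disorders: {appetite_change: 0.284, constipation: 0.215, ulcers: 0.501}
    cardiovascular_disorders: {dyspnea: 0.526, high_blood_pressure: 0.196, low_blood_pressure: 0.278}
    musculoskeletal_disorders: {sore_neck: 0.329, backache: 0.475, sore_leg_knee: 0.196}
  alternatives:
    night_shift: 0.672
    morning_shift: 0.328
security_24_48:
  label: "Security personnel working 24-48 hour shift patterns"
  criteria:
    sleep_disorders: 0.201
    personal_life_disorders: 0.145
    family_life_disorders: 0.121
    mental_disorders: 0.174
    digestive_disorders: 0.186
    cardiovascular_disorders: 0.075
    musculoskeletal_disorders: 0.098
  subcriteria:
    sleep_disorders: {sleeplessness: 0.785, hypnotics: 0.215}
    personal_life_disorders: {rest: 0.477, exercise: 0.523}
    family_life_disorders: {household_chores: 0.411, children_parents: 0.361, family_ceremonies: 0.228}
    mental_disorders: {headache_dizziness: 0.109, anger: 0.278, impatience: 0.198, depression: 0.415}
    digestive_disorders: {appetite_change: 0.312, constipation: 0.206, ulcers: 0.482}
    cardiovascular_disorders: {dyspnea: 0.389, high_blood_pressure: 0.227, low_blood_pressure: 0.384}
    musculoskeletal_disorders: {sore_neck: 0.175, backache: 0.423, sore_leg_knee: 0.402}
  alternatives:
    night_shift: 0.672
    evening_shift: 0.323
    morning_shift: 0.265
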