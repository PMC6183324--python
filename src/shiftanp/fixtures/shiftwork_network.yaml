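# Shift-work disorder decision network: 7 criteria (disorder categories),
# 20 sub-criteria (specific complaints from the Survey of Shiftworkers
# instrument), 3 alternatives (shift types).
#
# The published network figure does not enumerate its dependency edges; this
# bundled default encodes the hierarchy (goal -> criteria -> sub-criteria ->
# alternatives) plus inner dependence among the criteria
# (criteria_feedback: true), and is overridable: supply explicit `edges` or
# set criteria_feedback: false.
name: shiftwork
goal:
  id: goal
  label: Prioritize shift-work disorders
structure:
  hierarchy: true
  criteria_feedback: true
clusters:
  - id: criteria
    label: Shift-work disorder criteria
    kind: criteria
    members:
      - {id: sleep_disorders, label: Sleep disorders}
      - {id: personal_life_disorders, label: Personal life disorders}
      - {id: family_life_disorders, label: Family life disorders}
      - {id: mental_disorders, label: Mental disorders}
      - {id: digestive_disorders, label: Digestive disorders}
      - {id: cardiovascular_disorders, label: Cardiovascular disorders}
      - {id: musculoskeletal_disorders, label: Musculoskeletal disorders}
  - id: subcriteria
    label: Specific complaints
    kind: subcriteria
    members:
      - {id: sleeplessness, label: Sleeplessness or frequent wake-up during sleep, parent: sleep_disorders}
      - {id: hypnotics, label: Use of hypnotics, parent: sleep_disorders}
      - {id: rest, label: Rest, parent: personal_life_disorders}
      - {id: exercise, label: Exercise, parent: personal_life_disorders}
      - {id: household_chores, label: Lack of enough time for doing household chores, parent: family_life_disorders}
      - {id: children_parents, label: Attending to children and parents, parent: family_life_disorders}
      - {id: family_ceremonies, label: Attendance in familial ceremonies, parent: family_life_disorders}
      - {id: headache_dizziness, label: Headache and dizziness, parent: mental_disorders}
      - {id: anger, label: Anger, parent: mental_disorders}
      - {id: impatience, label: Impatience, parent: mental_disorders}
      - {id: depression, label: Depression, parent: mental_disorders}
      - {id: appetite_change, label: Increased/decreased appetite, parent: digestive_disorders}
      - {id: constipation, label: Constipation, parent: digestive_disorders}
      - {id: ulcers, label: Ulcers, parent: digestive_disorders}
      - {id: dyspnea, label: Dyspnea, parent: cardiovascular_disorders}
      - {id: high_blood_pressure, label: High blood pressure, parent: cardiovascular_disorders}
      - {id: low_blood_pressure, label: Low blood pressure, parent: cardiovascular_disorders}
      - {id: sore_neck, label: Sore neck, parent: musculoskeletal_disorders}
      - {id: backache, label: Backache, parent: musculoskeletal_disorders}
      - {id: sore_leg_knee, label: Sore leg and knee, parent: musculoskeletal_disorders}
  - id: alternatives
    label: Shift types
    kind: alternatives
    members:
      - {id: morning_shift, label: Morning shift}
      - {id: evening_shift, label: Evening shift}
      - {id: night_shift, label: Night shift}
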