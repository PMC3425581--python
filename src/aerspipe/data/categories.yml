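# Default adverse-event categories. Each category is a named list of coded
# reaction terms (MedDRA preferred-term style strings). The first four are
# single-term categories; the three broad categories ship as editable
# starting points and should be replaced with a study-specific term list.
Myalgia:
  terms: [myalgia]
Rhabdomyolysis:
  terms: [rhabdomyolysis]
Myositis:
  terms: [myositis]
Myopathy:
  terms: [myopathy]
Joints and Tendons:
  terms:
    - arthralgia
    - tendonitis
    - tendon disorder
    - tendon rupture
    - tendon pain
    - joint swelling
    - joint stiffness
Muscle Atrophy and Injury:
  terms:
    - muscle atrophy
    - muscle injury
    - muscle necrosis
    - muscle rupture
    - muscle haemorrhage
Muscle Coordination and Weakness:
  terms:
    - muscular weakness
    - muscle spasms
    - muscle rigidity
    - coordination abnormal
    - gait disturbance
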