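# Catalog of competing factor structures for the 20 PCL-5 items.
#
# Factor codes: In intrusion; Av avoidance; NACM negative alterations in
# cognitions and mood; AAR alterations in arousal and reactivity; Dy dysphoria;
# DA dysphoric arousal; AA anxious arousal; EB externalizing behavior;
# NA negative affect; An anhedonia.
items:
  - {code: B1, text: Intrusive thoughts}
  - {code: B2, text: Nightmares}
  - {code: B3, text: Flashbacks}
  - {code: B4, text: Emotional cue reactivity}
  - {code: B5, text: Physiological cue reactivity}
  - {code: C1, text: Avoidance of thoughts}
  - {code: C2, text: Avoidance of reminders}
  - {code: D1, text: Trauma-related amnesia}
  - {code: D2, text: Negative beliefs}
  - {code: D3, text: Distorted blame}
  - {code: D4, text: Pervasive negative emotional state}
  - {code: D5, text: Lack of interest}
  - {code: D6, text: Feeling detached}
  - {code: D7, text: Inability to experience positive emotions}
  - {code: E1, text: Irritability/aggression}
  - {code: E2, text: Recklessness}
  - {code: E3, text: Hypervigilance}
  - {code: E4, text: Exaggerated startle}
  - {code: E5, text: Difficulty concentrating}
  - {code: E6, text: Sleep disturbance}

models:
  dsm5:
    factors: [In, Av, NACM, AAR]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: NACM, D2: NACM, D3: NACM, D4: NACM, D5: NACM, D6: NACM, D7: NACM,
              E1: AAR, E2: AAR, E3: AAR, E4: AAR, E5: AAR, E6: AAR}
  dysphoria:
    factors: [In, Av, Dy, AAR]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: Dy, D2: Dy, D3: Dy, D4: Dy, D5: Dy, D6: Dy, D7: Dy,
              E1: Dy, E2: Dy, E3: AAR, E4: AAR, E5: Dy, E6: Dy}
  dysphoric_arousal:
    factors: [In, Av, NACM, DA, AA]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: NACM, D2: NACM, D3: NACM, D4: NACM, D5: NACM, D6: NACM, D7: NACM,
              E1: DA, E2: DA, E3: AA, E4: AA, E5: DA, E6: DA}
  anhedonia:
    factors: [In, Av, NA, An, DA, AA]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: NA, D2: NA, D3: NA, D4: NA, D5: An, D6: An, D7: An,
              E1: DA, E2: DA, E3: AA, E4: AA, E5: DA, E6: DA}
  externalizing:
    factors: [In, Av, NACM, EB, AA, DA]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: NACM, D2: NACM, D3: NACM, D4: NACM, D5: NACM, D6: NACM, D7: NACM,
              E1: EB, E2: EB, E3: AA, E4: AA, E5: DA, E6: DA}
  hybrid:
    factors: [In, Av, NA, An, EB, AA, DA]
    loading: {B1: In, B2: In, B3: In, B4: In, B5: In,
              C1: Av, C2: Av,
              D1: NA, D2: NA, D3: NA, D4: NA, D5: An, D6: An, D7: An,
              E1: EB, E2: EB, E3: AA, E4: AA, E5: DA, E6: DA}
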