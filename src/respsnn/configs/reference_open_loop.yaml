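network:
  name: open_loop+follower
  neurons:
  - Edec_TON
  - Edec_OUT
  - Idec_TON
  - Idec_OUT
  - EI_TON
  - EI_OUT
  - 'ON'
  - I_inc
  connections:
  - pre: Edec_TON
    post: Edec_TON
    K: 3
    P: 600
    plastic_tag: none
  - pre: Edec_TON
    post: Edec_OUT
    K: 1
    P: 5000
    plastic_tag: P_f
  - pre: Edec_OUT
    post: Edec_TON
    K: 1
    P: -2200
    plastic_tag: none
  - pre: Edec_OUT
    post: Idec_OUT
    K: 4
    P: -250
    plastic_tag: none
  - pre: Edec_OUT
    post: EI_TON
    K: 4
    P: 8000
    plastic_tag: none
  - pre: Edec_OUT
    post: EI_OUT
    K: 4
    P: -500
    plastic_tag: none
  - pre: Idec_TON
    post: Idec_TON
    K: 3
    P: 40
    plastic_tag: none
  - pre: Idec_TON
    post: Idec_OUT
    K: 4
    P: 500
    plastic_tag: none
  - pre: Idec_OUT
    post: Edec_OUT
    K: 1
    P: -1500
    plastic_tag: none
  - pre: Idec_OUT
    post: Idec_TON
    K: 3
    P: -5000
    plastic_tag: none
  - pre: Idec_OUT
    post: EI_OUT
    K: 4
    P: -350
    plastic_tag: none
  - pre: EI_TON
    post: EI_TON
    K: 3
    P: 40
    plastic_tag: none
  - pre: EI_TON
    post: EI_OUT
    K: 2
    P: 400
    plastic_tag: none
  - pre: EI_OUT
    post: Idec_TON
    K: 2
    P: 200
    plastic_tag: none
  - pre: EI_OUT
    post: EI_TON
    K: 2
    P: 1280
    plastic_tag: none
  - pre: 'ON'
    post: Edec_TON
    K: 4
    P: 1280
    plastic_tag: none
  - pre: EI_OUT
    post: I_inc
    K: 4
    P: 1500
    plastic_tag: none
  - pre: Edec_OUT
    post: I_inc
    K: 4
    P: -4000
    plastic_tag: none
  - pre: I_inc
    post: I_inc
    K: 2
    P: 900
    plastic_tag: P_a
  external_inputs: 1
  count_external_as_connections: true
lif:
  theta: 10.0
  leak_shift: 3
  refractory_steps: 1
  dt: 0.0005
fixedpoint:
  r_format: U0.18
  const_format: U0.14
  v_format: S17.18
backend: fixed
pulse_steps: 1
stim_source: I_inc
plasticity: null
encoders:
  volume:
    v_min: 0.2
    v_max: 2.0
  co2:
    baseline: 1.0
    span: 0.2
plant:
  wi: 1.0
  mbc: 1.0
  rr0: 56.0
  vt0: 2.0
  ti_frac: 0.35
  mass: 1.0
  damping: 72.0
  k0: 900.0
  k_knee: 0.7
  k_stiff: 0.5
  f_max: 900.0
  recruit_sat: 1.5
  vol_gain: 2.3428183634775213
  co2_ref: 1.0
  mbc0_rate: 0.1
  k_ex: 0.05390800541219115
  rr_gain: 8.0
  regression:
    a: -9.078842512122767
    b: 64.63949368959683
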