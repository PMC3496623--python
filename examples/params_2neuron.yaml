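N: 2
C:
- 1.0
- 1.0
theta: 12.0
E_L: 0.0
E_plus: 65.0
E_minus: -5.0
g_L:
- 0.5
- 0.5
G:
- - 0.0
  - 0.1
- - 0.15
  - 0.0
pop:
- E
- I
tau_syn:
- - 2.0
  - 3.0
- - 2.0
  - 3.0
profile_degree: 0
sigma_B: 4.0
sigma_R: 2.0
tau_sep: 1.0
i_ext:
  offsets:
  - 0.0
  values:
  - - 4.0
    - 4.0
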