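# Parameter set obtained after semi-manual tuning (version III).
version: III
gamma: 2.0
genes:
  BCL6:
    s0: 100.0
    d0: 0.05
    s1: 100.0
    d1: 0.138
    kon_init: 0.15
    koff_init: 1.0
  IRF4:
    s0: 2.1
    d0: 0.05
    s1: 160.0
    d1: 0.173
    kon_init: 0.007
    koff_init: 1.0
  BLIMP1:
    s0: 100.0
    d0: 0.007
    s1: 40.0
    d1: 0.173
    kon_init: 0.001
    koff_init: 1.0
theta:
  BCL6.BCL6: -0.2
  BCL6.IRF4: 0.0
  BCL6.BLIMP1: -1.0
  IRF4.BCL6: -50.0
  IRF4.IRF4: 11.0
  IRF4.BLIMP1: 50.0
  BLIMP1.BCL6: -0.5
  BLIMP1.IRF4: 0.0
  BLIMP1.BLIMP1: 0.0
  BCR.BCL6: -200.0
  CD40.IRF4: 10.0
H:
  BCL6.BCL6: 0.1
  BCL6.IRF4: 1.0
  BCL6.BLIMP1: 0.01
  IRF4.BCL6: 0.01
  IRF4.IRF4: 0.1
  IRF4.BLIMP1: 0.1
  BLIMP1.BCL6: 0.01
  BLIMP1.IRF4: 1.0
  BLIMP1.BLIMP1: 1.0
  BCR.BCL6: 0.001
  CD40.IRF4: 1.0
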