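# Parameter set selected by the automatized grid screen (version II).
version: II
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
    s0: 1.0
    d0: 0.05
    s1: 160.0
    d1: 0.173
    kon_init: 0.007
    koff_init: 1.0
  BLIMP1:
    s0: 1.0
    d0: 0.1733
    s1: 40.0
    d1: 0.173
    kon_init: 0.001
    koff_init: 1.0
theta:
  BCL6.BCL6: -0.2
  BCL6.IRF4: 0.0
  BCL6.BLIMP1: -1.0
  IRF4.BCL6: -100.0
  IRF4.IRF4: 5.0
  IRF4.BLIMP1: 40.0
  BLIMP1.BCL6: -20.0
  BLIMP1.IRF4: 0.0
  BLIMP1.BLIMP1: 0.0
  BCR.BCL6: -20.0
  CD40.IRF4: 40.0
H:
  BCL6.BCL6: 0.1
  BCL6.IRF4: 1.0
  BCL6.BLIMP1: 1.0
  IRF4.BCL6: 0.01
  IRF4.IRF4: 0.01
  IRF4.BLIMP1: 0.1
  BLIMP1.BCL6: 0.01
  BLIMP1.IRF4: 1.0
  BLIMP1.BLIMP1: 1.0
  BCR.BCL6: 1.0
  CD40.IRF4: 0.001
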