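# Reference parameter set for the gut-muscle axis model.
# Produced by anchor calibration (gutmuscle.calibrate) against the headline
# observables; see docs/methods.md for the procedure and residuals.
# All values are dimensionless; time unit = 1 hour.
a1: 0.28277921905644565
a2: 0.23998902974242745
a3: 0.005511089289543437
a4: 0.300384038080961
a5: 0.25207217266061305
a6: 0.3024862582999374
a7: 0.3040360363897821
a8: 0.636410512247715
c1: 8.13369368791701
c2: 0.6097912494668584
c3: 0.6033744705803027
c4: 0.08102061603766608
c5: 0.04847051228633426
c6: 0.05167759954333457
c7: 0.04097551247002868
d1: 0.8489761297523859
d2: 0.8000774587556487
d3: 1.7547319646380048
d4: 0.4850516044788922
d5: 0.1794136085301601
d6: 0.4880674093463035
d7: 0.4938289931261273
d8: 0.8407808793313644
l1: 0.05096686096440051
l2: 0.06165777137887778
l3: 0.10474839608970096
l4: 0.04609832031396473
l5: 0.11290794667051478
l6: 0.12296814456159577
K1: 1.0001053864959597
K2: 1.000213782946019
K3: 1.000183970609917
K4: 1.000360081802682
K5: 0.9996944089078232
K6: 0.9997470677315717
K: 2.1109333731096775
M: 1.7206899555675061
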