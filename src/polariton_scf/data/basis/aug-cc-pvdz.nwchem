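# aug-cc-pVDZ correlation-consistent basis (Dunning; Kendall, Dunning,
# Harrison diffuse augmentation), transcribed from the standard published
# tables.  Spherical d functions.
BASIS "ao basis" SPHERICAL PRINT
H    S
     13.0100000              0.0196850
      1.9620000              0.1379770
      0.4446000              0.4781480
      0.1220000              0.5012400
H    S
      0.1220000              1.0000000
H    S
      0.0297400              1.0000000
H    P
      0.7270000              1.0000000
H    P
      0.1410000              1.0000000
C    S
   6665.0000000              0.0006920             -0.0001460
   1000.0000000              0.0053290             -0.0011540
    228.0000000              0.0270770             -0.0057250
     64.7100000              0.1017180             -0.0233120
     21.0600000              0.2747400             -0.0639550
      7.4950000              0.4485640             -0.1499810
      2.7970000              0.2850740             -0.1272620
      0.5215000              0.0152040              0.5445290
      0.1596000             -0.0031910              0.5804960
C    S
      0.1596000              1.0000000
C    S
      0.0469000              1.0000000
C    P
      9.4390000              0.0381090
      2.0020000              0.2094800
      0.5456000              0.5085570
      0.1517000              0.4688420
C    P
      0.1517000              1.0000000
C    P
      0.0404100              1.0000000
C    D
      0.5500000              1.0000000
C    D
      0.1510000              1.0000000
N    S
   9046.0000000              0.0007000             -0.0001530
   1357.0000000              0.0053890             -0.0012080
    309.3000000              0.0274060             -0.0059920
     87.7300000              0.1032070             -0.0245440
     28.5600000              0.2787230             -0.0674590
     10.2100000              0.4485400             -0.1580780
      3.8380000              0.2782380             -0.1218310
      0.7466000              0.0154400              0.5490030
      0.2248000             -0.0028640              0.5788150
N    S
      0.2248000              1.0000000
N    S
      0.0612400              1.0000000
N    P
     13.5500000              0.0399190
      2.9170000              0.2171690
      0.7973000              0.5103190
      0.2185000              0.4622140
N    P
      0.2185000              1.0000000
N    P
      0.0561100              1.0000000
N    D
      0.8170000              1.0000000
N    D
      0.2300000              1.0000000
O    S
  11720.0000000              0.0007100             -0.0001600
   1759.0000000              0.0054700             -0.0012630
    400.8000000              0.0278370             -0.0062670
    113.7000000              0.1048000             -0.0257160
     37.0300000              0.2830620             -0.0709240
     13.2700000              0.4487190             -0.1654110
      5.0250000              0.2709520             -0.1169550
      1.0130000              0.0154580              0.5573680
      0.3023000             -0.0025850              0.5727590
O    S
      0.3023000              1.0000000
O    S
      0.0789600              1.0000000
O    P
     17.7000000              0.0430180
      3.8540000              0.2289130
      1.0460000              0.5087280
      0.2753000              0.4605310
O    P
      0.2753000              1.0000000
O    P
      0.0685600              1.0000000
O    D
      1.1850000              1.0000000
O    D
      0.3320000              1.0000000
END
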