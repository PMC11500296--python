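# 6-31G split-valence basis (Hehre, Ditchfield, Pople and co-workers),
# transcribed from the standard published tables.
BASIS "ao basis" PRINT
H    S
     18.7311370              0.03349460
      2.8253937              0.23472695
      0.6401217              0.81375733
H    S
      0.1612778              1.0000000
C    S
   3047.5249000              0.0018347
    457.3695100              0.0140373
    103.9486900              0.0688426
     29.2101550              0.2321844
      9.2866630              0.4679413
      3.1639270              0.3623120
C    SP
      7.8682724             -0.1193324              0.0689991
      1.8812885             -0.1608542              0.3164240
      0.5442493              1.1434564              0.7443083
C    SP
      0.1687144              1.0000000              1.0000000
N    S
   4173.5110000              0.0018348
    627.4579000              0.0139950
    142.9021000              0.0685870
     40.2343300              0.2322410
     13.0327000              0.4690700
      4.6032230              0.3604550
N    SP
     11.6263580             -0.1149610              0.0675800
      2.7162800             -0.1691180              0.3239070
      0.7722180              1.1458520              0.7408950
N    SP
      0.2120313              1.0000000              1.0000000
O    S
   5484.6717000              0.0018311
    825.2349500              0.0139501
    188.0469600              0.0684451
     52.9645000              0.2327143
     16.8975700              0.4701930
      5.7996353              0.3585209
O    SP
     15.5396160             -0.1107775              0.0708743
      3.5999336             -0.1480263              0.3397528
      1.0137618              1.1307670              0.7271586
O    SP
      0.2700058              1.0000000              1.0000000
END
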