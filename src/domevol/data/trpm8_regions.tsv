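region	start	end
MHR1	117	245
MHR2	246	352
MHR3	353	550
MHR4	551	692
TM-1	691	710
Loop-1	711	730
TM-2	731	758
Loop-2	759	802
TM-3	803	820
Loop-3	821	829
TM-4	830	848
Loop-4	849	866
TM-5	867	885
Pore region	886	954
TM-6	955	977
N-terminal	1	692
TM and loop region	693	989
C-terminal	978	1104
Localization and tetramerization	40	86
Coiled coil (N-terminus)	594	628
Channel gating	799	805
Voltage sensor	842	856
TRP-domain (990-1025)	990	1025
TRP-domain (993-1016)	993	1016
TRP-Box	993	998
Self-interacting sites	1007	1047
Coiled coil (C-terminus, 1064-1104)	1064	1104
Coiled coil (C-terminus, 1070-1104)	1070	1104
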