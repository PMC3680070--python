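pair_id	gold
B.d267.s0.p14	T
B.d418.s0.p0	T
B.d418.s0.p1	T
B.d506.s0.p8	T
B.d833.s0.p15	T
B.d833.s0.p14	T
B.d594.s0.p0	T
B.d296.s2.p20	T
B.d296.s2.p25	T
B.d541.s0.p0	T
B.d546.s0.p20	T
A.d28.s234.p1	T
B.d765.s0.p14	T
B.d296.s2.p23	T
B.d267.s0.p18	T
B.d833.s0.p35	T
B.d765.s0.p10	T
B.d833.s0.p34	T
B.d506.s0.p4	T
B.d833.s0.p7	T
B.d506.s0.p11	T
B.d833.s0.p29	T
B.d833.s0.p32	T
A.d60.s528.p0	F
B.d180.s0.p0	F
A.d114.s961.p0	F
B.d93.s0.p9	F
B.d749.s0.p2	F
B.d639.s0.p0	F
B.d334.s0.p0	F
A.d141.s1189.p0	F
B.d485.s0.p2	F
A.d157.s1329.p4	F
A.d60.s529.p0	F
A.d199.s1701.p0	F
A.d161.s1355.p0	F
B.d357.s0.p1	F
A.d195.s1663.p2	F
A.d151.s1288.p1	F
B.d485.s0.p4	F
B.d814.s0.p26	F
B.d14.s0.p4	F
A.d39.s340.p0	F
B.d307.s0.p4	F
B.d35.s4.p9	F
L.d35.s1.p1	F
B.d14.s1.p2	F
I.d11.s28.p1	F
L.d13.s0.p1	F
A.d78.s669.p2	F
B.d223.s0.p9	F
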