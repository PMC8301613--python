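patient	diagnosis	karyotype	mapped_reads	fusion	rpm
#097	AML	46,XY,t(8;21)(q22;q22)[17]/46,XY[3]	33369	RUNX1-RUNX1T1	13828
#112	AML	46,XX,inv(16)(p13.1q22)[20]	35387	CBFB-MYH11	2560
#152	AML-MRC	46,XX[20]	48535	KMT2A-MLLT10	1551
#176	AML	46,XY[20]	44467	-	-
#188	aCML	47,XY,+6[20]	20447	-	-
#191	AML	46,XX[20]	84383	-	-
#205	AML	46,XY[20]	27515	-	-
#220	t-AML	46,XX,inv(16)(p13.1q22)[20]	48261	CBFB-MYH11	2546
#226	AML	46,XX,i(7)(p10),-9,-9,+mar1,+mar2[20]	31830	-	-
#231	MPAL	46,XY,add(17)(p11.2)[12]/46,XY,del(17)(p?)[6]/46,XY[2]	167249	NUP214-ABL	2255
#232	AML	46,XY,del(11)(p?)[1]/46,XY[19]	50825	-	-
#238	AML-MRC	46,XY,t(4;12)(q12;p13)[14]/46,XY[6]	30749	ETV6-CHIC2	1524
#240	AML	46,XY,t(8;21)(q22;q22.1)[3]/46,idem,-Y[14]/46,idem,del(9)(q?)[2]/46,XY[1]	56151	RUNX1-RUNX1T1	166556
#248	AML	46,XX,+8[2]/46,XX[18]	13875	-	-
#256	AML	47,XY,+10[3]/46,XY[17]	35635	-	-
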