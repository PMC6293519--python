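flybase_id	gene	amplicons	mean_z
FBgn0027084	Aats-lys	DRSC25618	3.62
FBgn0000043	Act42A	DRSC04835	4.46
FBgn0000044	Act57B	DRSC04042	5.98
FBgn0000042	Act5C	DRSC17723;DRSC25024	7.32;8.13
FBgn0000045	Act79B	DRSC11604	3.69
FBgn0087035	AGO2	DRSC10847;DRSC40785	4.89;3.95
FBgn0041188	Atx2	DRSC40788	4.40
FBgn0000212	brm	DRSC11330;DRSC26226	4.33;9.95
FBgn0029856	CG11700	DRSC23384	3.67
FBgn0033507	CG12909	DRSC27706	3.07
FBgn0039601	CG1523	DRSC15033;DRSC26315	3.49;3.10
FBgn0035569	CG15876	DRSC08484	3.71
FBgn0067622	LSm-4	DRSC02845	3.44
FBgn0032240	CG17768	DRSC02845	3.44
FBgn0034325	CG18539	DRSC06766	3.12
FBgn0034326	CG18540	DRSC06767	3.10
FBgn0011824	CG4038	DRSC25331	3.79
FBgn0036991	CG5872	DRSC11785	3.64
FBgn0035872	CG7185	DRSC10781	3.49
FBgn0259236	comm3	DRSC09995	3.24
FBgn0031831	COX5BL	DRSC27300	6.17
FBgn0263093	CR43361	DRSC23926	3.19
FBgn0033260	Cul4	DRSC27185	4.46
FBgn0086901	cv-c	DRSC27016	4.33
FBgn0002413	dco	DRSC16929	3.26
FBgn0034246	Dcr-2	DRSC29436	3.53
FBgn0260049	flr	DRSC09787	3.11
FBgn0034964	IntS1	DRSC04343;DRSC27942	9.26;5.92
FBgn0026679	IntS4	DRSC17810	5.00
FBgn0036570	IntS9	DRSC10493	3.52
FBgn0004419	me31B	DRSC03569	3.30
FBgn0035473	mge	DRSC08721	3.58
FBgn0027378	MRG15	DRSC16731	4.68
FBgn0085417	natalisin	DRSC23390	3.78
FBgn0032725	Nedd8	DRSC02092	6.04
FBgn0041102	ocn	DRSC17020	3.25
FBgn0020626	Osbp	DRSC16779	3.21
FBgn0044826	Pak3	DRSC26832	4.48
FBgn0050382	CG30382	DRSC07515	3.16
FBgn0263121	Prosalpha1	DRSC07515	3.16
FBgn0086134	Prosalpha2	DRSC28078	5.52
FBgn0261394	Prosalpha3	DRSC04644	3.19
FBgn0004066	Prosalpha4	DRSC20271	4.03
FBgn0020618	Rack1	DRSC03405;DRSC23796	5.15;6.14
FBgn0033897	Rcd1	DRSC07116;DRSC23713	3.57;5.29
FBgn0015283	Rpn10	DRSC11876	4.34
FBgn0028686	Rpt3	DRSC23412	3.58
FBgn0266666	Sem1	DRSC02282	3.50
FBgn0003392	shi	DRSC20373;DRSC29498	5.20;5.03
FBgn0019890	Smg5	DRSC03124	3.63
FBgn0264357	SNF4Agamma	DRSC16847;DRSC40676	4.95;4.12
FBgn0011715	Snr1	DRSC12369	6.12
FBgn0034175	ste24b	DRSC07315	3.24
FBgn0033902	Tango7	DRSC07142;DRSC26908	3.95;5.70
FBgn0024921	Trn	DRSC25104	4.88
FBgn0011726	tsr	DRSC04718;DRSC40832	6.64;6.60
FBgn0035124	ttm2	DRSC08268	3.84
FBgn0039530	Tusp	DRSC15838	3.17
FBgn0023143	Uba1	DRSC07567	4.15
FBgn0263697	Uba3	DRSC06377	3.27
FBgn0035853	UbcE2M	DRSC10828	6.22
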