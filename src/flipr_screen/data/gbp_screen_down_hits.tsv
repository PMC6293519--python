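flybase_id	gene	amplicons	mean_z
FBgn0033246	ACC	DRSC06059	-3.15
FBgn0025725	alphaCOP	DRSC08706	-5.27
FBgn0003884	alphaTub84B	DRSC12622;DRSC25011	-3.32;-3.09
FBgn0013749	Arf102F	DRSC17195	-4.18
FBgn0033062	Ars2	DRSC04893	-3.06
FBgn0010217	ATPsynbeta	DRSC17194	-3.48
FBgn0014127	barr	DRSC03488	-3.52
FBgn0025724	beta'COP	DRSC03492;DRSC26650	-4.27;-5.03
FBgn0259876	Cap-G	DRSC21805	-4.04
FBgn0022213	Cas	DRSC26857	-3.13
FBgn0022942	Cbp80	DRSC18450	-3.12
FBgn0012058	Cdc27	DRSC11112	-3.3
FBgn0030510	CG12177	DRSC19437	-7.01
FBgn0033429	CG12929	DRSC06242	-6.12
FBgn0031023	CG14200	DRSC19555	-3.02
FBgn0266917	CG16941	DRSC15166	-3.92
FBgn0031498	CG17260	DRSC00497	-8.46
FBgn0083978	CG17672	DRSC09230	-3.49
FBgn0035205	CG2469	DRSC08562	-3.14
FBgn0031266	CG2807	DRSC00535	-5.48
FBgn0031493	CG3605	DRSC00619	-5.79
FBgn0058198	CG40198	DRSC21068	-3.12
FBgn0035983	CG4080	DRSC10398	-6.77
FBgn0086758	chinmo	DRSC28547	-3.26
FBgn0259993	CR42491	DRSC25025	-4.52
FBgn0028836	CSN7	DRSC06807;DRSC06808	-3.03;-3.07
FBgn0025455	CycT	DRSC11124	-3.6
FBgn0086687	Desat1	DRSC23578	-5.23
FBgn0260635	Diap1	DRSC11404	-4.59
FBgn0039183	Dis3	DRSC16034	-3.99
FBgn0004638	drk	DRSC07606	-3.52;-3.54
FBgn0034975	enok	DRSC04096	-3.07
FBgn0033859	fand	DRSC39027	-4.62
FBgn0004656	fs(1)h	DRSC29017	-3.39
FBgn0004435	Galphaq	DRSC07432	-3.36
FBgn0001105	Gbeta13F	DRSC20247	-5.32
FBgn0014189	Hel25E	DRSC03342	-3.76
FBgn0053818	His3:CG33818	DRSC21267	-4.05
FBgn0015393	hoip	DRSC03546	-5.3
FBgn0001218	Hsc70-3	DRSC25105	-3.05
FBgn0266599	Hsc70-4	DRSC29729	-3.32
FBgn0010051	Itp-r83A	DRSC12354	-6.95
FBgn0004378	Klp61F	DRSC28179	-3.31
FBgn0001491	l(1)10Bb	DRSC20346	-3.32
FBgn0001986	l(2)35Df	DRSC03560	-4.51
FBgn0011640	lark	DRSC11362;DRSC25108	-4.28;-5.71
FBgn0035889	mkg-p	DRSC10777	-3.13
FBgn0032921	Mpp6	DRSC03169	-3.77
FBgn0035132	mthl10	DRSC39158	-3.58
FBgn0086707	ncm	DRSC02179	-5.76
FBgn0026401	Nipped-B	DRSC07815;DRSC29151	-3.27;-3.01
FBgn0014366	noi	DRSC12383	-3.03
FBgn0005648	Pabp2	DRSC07501	-3.32
FBgn0259214	PMCA	DRSC17154	-4.59
FBgn0010590	Prosbeta1	DRSC07159	-7.45
FBgn0026380	Prosbeta3	DRSC16801	-3.72
FBgn0032006	Pvr	DRSC36840	-5.7
FBgn0003189	r	DRSC19813;DRSC19814	-4.38;-4.44
FBgn0020255	Ran	DRSC28160	-4.51
FBgn0003205	Ras85D	DRSC39132	-3.42
FBgn0031868	Rat1	DRSC02044	-3.31
FBgn0011704	RnrS	DRSC07533;DRSC23541	-3.50;-3.79
FBgn0010173	RpA-70	DRSC16830	-3.63
FBgn0015805	Rpd3	DRSC08696	-3.32
FBgn0262955	RpII140	DRSC16831	-4.09
FBgn0003277	RpII215	DRSC20280	-3.11
FBgn0028694	Rpn11	DRSC03422	-5.4
FBgn0028689	Rpn6	DRSC07541	-4.56
FBgn0028688	Rpn7	DRSC16841	-4.81
FBgn0002787	Rpn8	DRSC04624	-3.37
FBgn0028684	Rpt5	DRSC16842	-3.02
FBgn0038269	Rrp6	DRSC16223	-3.87
FBgn0262601	SmB	DRSC03437	-3.07
FBgn0261789	SmD2	DRSC12536	-3.88
FBgn0261790	SmE	DRSC02680	-4.03
FBgn0028982	Spt6	DRSC18836	-4.58
FBgn0038810	Srp72	DRSC15800	-3.69
FBgn0045073	Stim	DRSC20158	-4.54
FBgn0003575	su(sable)	DRSC18839	-3.15
FBgn0030365	Tango4	DRSC23475	-3.85
FBgn0035713	velo	DRSC08841	-3.45
FBgn0003978	vls	DRSC02101	-6.77
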