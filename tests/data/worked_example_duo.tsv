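[Header]
Content	worked example duo excerpt
Num SNPs	18
Num Samples	2
[Data]
Sample ID	SNP Name	Chr	Position	GType	B Allele Freq	Log R Ratio
HM_MOLE	exm870797	6	1000000	BB	0.9841	0.0000
HM_MOLE	exm2271913	6	2000000	AB	0.4887	0.0000
HM_MOLE	exm1163669	6	3000000	BB	0.9737	0.0000
HM_MOLE	exm151810	6	4000000	AB	0.4712	0.0000
HM_MOLE	exm363078	6	5000000	BB	0.9788	0.0000
HM_MOLE	exm1588790	6	6000000	BB	0.9921	0.0000
HM_MOLE	exm717089	6	7000000	AA	0.0089	0.0000
HM_MOLE	exm1436659	6	8000000	AA	0.0058	0.0000
HM_MOLE	exm747290	6	9000000	AB	0.4611	0.0000
HM_MOLE	exm2265754	6	10000000	AA	0.0042	0.0000
HM_MOLE	exm779139	6	11000000	AB	0.5202	0.0000
HM_MOLE	exm1083876	6	12000000	AA	0.0022	0.0000
HM_MOLE	exm-rs6929796	6	13000000	AB	0.5850	0.0000
HM_MOLE	exm1021627	6	14000000	BB	0.9553	0.0000
HM_MOLE	exm44591	6	15000000	BB	0.9822	0.0000
HM_MOLE	exm2259465	6	16000000	AA	0.0043	0.0000
HM_MOLE	exm2267990	6	17000000	AA	0.0102	0.0000
HM_MOLE	exm-rs10472828	6	18000000	AB	0.4670	0.0000
HM_BLOOD	exm870797	6	1000000	BB	0.9865	0.0000
HM_BLOOD	exm2271913	6	2000000	AB	0.4551	0.0000
HM_BLOOD	exm1163669	6	3000000	BB	0.9901	0.0000
HM_BLOOD	exm151810	6	4000000	AB	0.4921	0.0000
HM_BLOOD	exm363078	6	5000000	AB	0.4917	0.0000
HM_BLOOD	exm1588790	6	6000000	AB	0.4467	0.0000
HM_BLOOD	exm717089	6	7000000	AA	0.0002	0.0000
HM_BLOOD	exm1436659	6	8000000	AA	0.0010	0.0000
HM_BLOOD	exm747290	6	9000000	BB	0.9738	0.0000
HM_BLOOD	exm2265754	6	10000000	BB	0.9870	0.0000
HM_BLOOD	exm779139	6	11000000	AA	0.0056	0.0000
HM_BLOOD	exm1083876	6	12000000	AB	0.4597	0.0000
HM_BLOOD	exm-rs6929796	6	13000000	AA	0.0076	0.0000
HM_BLOOD	exm1021627	6	14000000	AA	0.0156	0.0000
HM_BLOOD	exm44591	6	15000000	AA	0.0233	0.0000
HM_BLOOD	exm2259465	6	16000000	AB	0.4864	0.0000
HM_BLOOD	exm2267990	6	17000000	BB	0.9968	0.0000
HM_BLOOD	exm-rs10472828	6	18000000	BB	0.9919	0.0000
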