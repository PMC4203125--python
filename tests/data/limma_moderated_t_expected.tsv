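gene	t	p
g001	 5.01643283991	0.0051333160329
g002	 8.21816215108	0.0006507457459
g003	11.06657146796	0.0001758462876
g004	 7.98554078878	0.0007369384676
g005	 2.70217038850	0.0466866628132
g006	 5.85656080709	0.0027387987068
g007	 7.93543593475	0.0007572676860
g008	 7.80027677262	0.0008155709340
g009	 1.17115103221	0.2987627023292
g010	 0.32410876394	0.7601078826307
g011	-2.59841230275	0.0525491634923
g012	-0.15382300105	0.8842852369885
g013	-0.40882683971	0.7010481758702
g014	-0.21885291142	0.8361654960868
g015	-1.55802623943	0.1851509659266
g016	-0.36988856570	0.7279232898098
g017	-1.63233629407	0.1687741206903
g018	-1.09144549501	0.3290631532993
g019	 2.20785908958	0.0831870259294
g020	 0.40101869481	0.7063985463600
g021	 2.16458133290	0.0876399805026
g022	-0.27928507062	0.7921763741235
g023	-0.41374982262	0.6976850830412
g024	 1.99470550340	0.1077631919682
g025	 0.24498544744	0.8170462357631
g026	 1.21219182640	0.2841588557248
g027	 0.56219996588	0.6003346063657
g028	-0.45221903073	0.6716871596985
g029	 0.69083559287	0.5230563040245
g030	 1.33879909637	0.2431497451756
g031	-0.24183224481	0.8193457064921
g032	-0.05572264061	0.9579075280318
g033	 0.19141748207	0.8563800274455
g034	 0.39151011298	0.7129407489528
g035	 1.13438156213	0.3124178040884
g036	-0.38977993213	0.7141342766778
g037	 1.58059477010	0.1800155950422
g038	 1.01602145077	0.3601810460881
g039	-1.68267140349	0.1585180569314
g040	 0.77651970350	0.4755556517419
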