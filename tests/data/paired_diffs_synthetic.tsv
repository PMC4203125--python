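gene	r1	r2	r3
g001	0.72433941	0.38272718	1.06087095
g002	0.53333333	0.67842613	0.53736703
g003	0.81669616	0.89541404	0.70876595
g004	0.47728992	0.5537985	0.5345661
g005	0.19070104	0.23779007	0.89811118
g006	0.40594693	0.92527903	0.80373311
g007	0.72030596	0.57636008	0.50806838
g008	0.51216191	0.82535901	0.77401384
g009	0.06607533	0.12036338	0.0431353
g010	0.52277846	-0.44240342	0.10947687
g011	-0.08674328	-0.20010858	-0.30716902
g012	0.13150922	0.07302468	-0.25118062
g013	-0.05909075	0.18734487	-0.25859445
g014	-0.15458202	0.03895438	0.06424876
g015	-0.12096532	-0.32963858	0.01918699
g016	0.09498491	-0.22652498	0.03075894
g017	-0.1060408	-0.13341197	-0.07636433
g018	-0.07934948	-0.11247189	-0.02371954
g019	0.4844965	0.26840036	-0.00446906
g020	0.04584194	-0.03587555	0.07067051
g021	0.13397094	0.12313285	0.15805501
g022	-0.35576602	0.29734195	-0.05882518
g023	-0.20671684	0.3238555	-0.29395044
g024	0.24008611	-0.00382862	0.28225308
g025	-0.0371157	0.10098275	-0.01278488
g026	0.23631204	0.08299934	-0.02504482
g027	0.09205103	-0.02889234	0.05111878
g028	-0.15459438	0.2384361	-0.24178432
g029	-0.29878609	0.1620451	0.46945554
g030	0.05197811	0.37112516	-0.01631929
g031	-0.09901791	0.26793413	-0.25647455
g032	-0.46812421	0.17015492	0.27031678
g033	0.07587903	0.13500896	-0.16081668
g034	-0.01767743	-0.01799111	0.11819927
g035	0.17447143	-0.19637386	0.55548504
g036	-0.01387768	-0.20918289	0.11852878
g037	0.12222827	0.11124864	0.07174577
g038	-0.04374954	0.24752921	0.05537232
g039	-0.09172338	-0.33561933	-0.02309465
g040	-0.00817286	0.1783534	0.00446048
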