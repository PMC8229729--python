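cell_id	regime	noise_free_response
C0001	1	7.473371649
C0002	1	5.503551791
C0003	0	2.070495667
C0004	0	3.003065419
C0005	1	6.916065451
C0006	1	5.536989231
C0007	1	5.632792896
C0008	0	2.775798489
C0009	0	2.876539483
C0010	2	9.985792976
C0011	2	9.478136659
C0012	1	5.502198305
C0013	1	5.704391957
C0014	2	9.310708247
C0015	1	6.016361228
C0016	2	8.097693566
C0017	2	8.266665825
C0018	2	9.213414374
C0019	2	8.096041928
C0020	2	8.01433623
C0021	1	6.570979492
C0022	2	9.784609468
C0023	0	0.0104627473
C0024	2	8.071303708
C0025	1	5.513966095
C0026	1	5.521594079
C0027	2	8.050451136
C0028	1	5.510353893
C0029	2	8.55628915
C0030	2	8.205439348
C0031	1	5.565998407
C0032	0	4.610344815
C0033	2	8.14170216
C0034	1	5.900213966
C0035	1	5.514857374
C0036	1	5.795113201
C0037	0	1.913288785
C0038	2	8.18236852
C0039	1	5.64959231
C0040	2	9.824212957
C0041	0	0.7974409028
C0042	1	5.502584154
C0043	2	9.995779776
C0044	2	9.740226844
C0045	2	8.500571631
C0046	1	6.048153086
C0047	0	1.035189047
C0048	0	1.391527233
C0049	2	9.120052726
C0050	0	0.7936441399
C0051	2	9.004114159
C0052	2	8.566671522
C0053	1	5.752553238
C0054	0	1.434086239
C0055	1	6.096356004
C0056	0	0.4882689237
C0057	0	2.592850601
C0058	2	9.954250078
C0059	1	5.730349418
C0060	2	8.219548522
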