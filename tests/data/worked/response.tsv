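drug_id	C0001	C0002	C0003	C0004	C0005	C0006	C0007	C0008	C0009	C0010	C0011	C0012	C0013	C0014	C0015	C0016	C0017	C0018	C0019	C0020	C0021	C0022	C0023	C0024	C0025	C0026	C0027	C0028	C0029	C0030	C0031	C0032	C0033	C0034	C0035	C0036	C0037	C0038	C0039	C0040	C0041	C0042	C0043	C0044	C0045	C0046	C0047	C0048	C0049	C0050	C0051	C0052	C0053	C0054	C0055	C0056	C0057	C0058	C0059	C0060
worked_drug	7.172505679169017	5.3807191385995345	2.148884058975117	2.9740554723035375	6.805842342623368	5.611127317697295	6.260930327058124	3.434906006623166	2.5072539841069776	9.477006218229032	9.684891054598845	5.483852570087509	5.972042554218415	9.220552891106196	5.808898140551451	8.268383463268947	8.43968975544777	9.348290481189935	8.049841036212625	8.283392122938494	6.79874929261367	9.429012268512363	0.0545634327925595	7.74868438720884	5.582491647346861	5.086007059654771	8.227447233044307	5.576720680310796	8.05224117245683	8.551592210962719	6.047084711282522	4.878721796700176	7.928977236249104	5.81002069076088	5.418052483201691	5.996771905465857	2.5604079700035864	7.9695901714027055	5.614882047670847	10.08115707261397	1.4627755560930258	5.491783229727324	9.929734212523208	10.243595280343829	8.63836056980448	5.613621058869727	1.5702297949445172	1.4187381924701579	9.807696902036149	1.168924555770349	9.685865758224757	8.70986059219885	6.079855120228962	1.2657577369580748	6.310347903545397	0.6062353004287909	2.370054100246369	9.908865343538281	5.0572474766292315	8.962399213525932
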