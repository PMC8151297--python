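marker_id	maf	ng	na	gd	he
AB-gCAPS-001	0.564	3	2	0.492	0.256
AB-gCAPS-002	0.609	3	2	0.476	0.696
AB-gCAPS-003	0.587	2	2	0.485	0.826
AB-gCAPS-004	1.000	1	1	0.000	0.000
AB-gCAPS-005	0.750	3	2	0.375	0.250
AB-gCAPS-006	1.000	1	1	0.000	0.000
AB-gCAPS-007	1.000	1	1	0.000	0.000
AB-gCAPS-008	0.694	2	2	0.425	0.613
AB-gCAPS-009	0.975	2	2	0.049	0.000
AB-gCAPS-012	0.700	2	2	0.420	0.000
AB-gCAPS-013	0.724	3	2	0.400	0.079
AB-gCAPS-015	0.720	3	2	0.404	0.463
AB-gCAPS-016	0.744	2	2	0.381	0.513
AB-gCAPS-017	0.738	2	2	0.387	0.525
AB-gCAPS-018	0.750	2	2	0.375	0.500
AB-gCAPS-019	0.732	3	2	0.393	0.341
AB-gCAPS-020	0.659	3	2	0.450	0.390
AB-gCAPS-021	0.756	2	2	0.369	0.488
AB-gCAPS-022	0.793	3	2	0.329	0.317
AB-gCAPS-024	0.683	2	2	0.433	0.634
AB-gCAPS-025	0.765	2	2	0.360	0.000
AB-gCAPS-026	0.770	2	2	0.354	0.459
AB-gCAPS-028	0.650	2	2	0.455	0.700
AB-gCAPS-030	0.610	2	2	0.476	0.000
AB-gCAPS-031	0.951	2	2	0.093	0.098
AB-gCAPS-032	1.000	1	1	0.000	0.000
AB-gCAPS-033	0.586	3	2	0.485	0.371
AB-gCAPS-034	0.561	3	2	0.493	0.146
AB-gCAPS-035	0.598	3	2	0.481	0.756
AB-gCAPS-036	0.500	3	2	0.500	0.294
AB-gCAPS-037	1.000	1	1	0.000	0.000
AB-gCAPS-038	0.817	2	2	0.299	0.366
AB-gCAPS-039	0.549	3	2	0.495	0.512
AB-gCAPS-041	0.537	3	2	0.497	0.585
AB-gCAPS-042	0.625	3	2	0.469	0.500
AB-gCAPS-043	0.662	3	2	0.448	0.618
AB-gCAPS-045	0.793	3	2	0.329	0.366
AB-gCAPS-047	0.855	2	2	0.248	0.289
AB-gCAPS-048	0.694	3	2	0.425	0.226
AB-gCAPS-050	0.750	3	2	0.375	0.289
AB-gCAPS-051	0.634	3	2	0.464	0.244
AB-gCAPS-052	0.615	3	2	0.473	0.205
AB-gCAPS-053	0.577	3	2	0.488	0.692
AB-gCAPS-054	0.973	2	2	0.053	0.000
AB-gCAPS-055	0.625	2	2	0.469	0.750
AB-gCAPS-056	0.771	3	2	0.353	0.057
AB-gCAPS-058	0.577	3	2	0.488	0.128
AB-gCAPS-059	0.524	3	2	0.499	0.610
AB-gCAPS-061	0.608	3	2	0.477	0.135
AB-gCAPS-062	0.671	3	2	0.442	0.171
AB-gCAPS-063	0.768	2	2	0.356	0.463
AB-gCAPS-064	0.775	2	2	0.349	0.450
AB-gCAPS-065	0.713	3	2	0.410	0.125
AB-gCAPS-066	0.632	2	2	0.465	0.000
AB-gCAPS-068	0.775	3	2	0.349	0.350
AB-gCAPS-070	0.585	2	2	0.485	0.000
AB-gCAPS-071	0.615	2	2	0.473	0.000
AB-gCAPS-072	0.600	2	2	0.480	0.000
AB-gCAPS-073	0.848	2	2	0.257	0.000
AB-gCAPS-078	0.634	3	2	0.464	0.098
AB-gCAPS-081	0.613	3	2	0.475	0.025
AB-gCAPS-082	0.667	2	2	0.444	0.000
AB-gCAPS-083	0.526	3	2	0.499	0.231
AB-gCAPS-084	1.000	1	1	0.000	0.000
AB-gCAPS-086	0.675	2	2	0.439	0.000
AB-gCAPS-087	0.671	3	2	0.442	0.073
AB-gCAPS-088	0.878	3	2	0.214	0.049
AB-gCAPS-089	0.850	3	2	0.255	0.100
AB-gCAPS-090	0.902	3	2	0.176	0.098
AB-gCAPS-093	0.984	2	2	0.031	0.031
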