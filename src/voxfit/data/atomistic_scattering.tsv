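# 5-Gaussian electron scattering factors f(s) = sum_k A_k exp(-B_k s^2), s = sin(theta)/lambda
# International Tables for Crystallography Vol. C, Table 4.3.2.2 (neutral atoms); B_k in A^2
type	A1	A2	A3	A4	A5	B1	B2	B3	B4	B5
H	0.0349	0.1201	0.1970	0.0573	0.1195	0.5347	3.5867	12.3471	18.9525	38.6269
C	0.0893	0.2563	0.7570	1.0487	0.3575	0.2465	1.7100	6.4094	18.6113	50.2523
N	0.1022	0.3219	0.7982	0.8197	0.1715	0.2451	1.7481	6.1925	17.3894	48.1431
O	0.0974	0.2921	0.6910	0.6990	0.2039	0.2067	1.3815	4.6943	12.7105	32.4726
S	0.2497	0.5628	1.3899	2.1865	0.7715	0.2681	1.6711	7.0267	19.5377	50.3888
P	0.2548	0.6106	1.4541	2.3204	0.8477	0.2908	1.8740	8.5176	24.3434	63.2996
F	0.1083	0.3175	0.6487	0.5846	0.1421	0.2057	1.3439	4.2788	11.3932	28.7881
Cl	0.2443	0.5397	1.3919	2.0197	0.6621	0.2468	1.5242	6.1537	16.6687	42.3086
Br	0.4798	1.1948	1.8695	2.6953	0.8203	0.2504	1.5963	6.9653	19.8492	50.3233
I	0.7047	1.9484	2.5940	4.1526	1.5057	0.2455	1.8638	6.7639	21.8007	56.4395
Na	0.2142	0.6853	0.7692	1.6589	1.4482	0.3334	2.3446	10.0830	48.3037	138.2700
Mg	0.2314	0.6866	0.9677	2.1882	1.1339	0.3278	2.2720	10.9241	39.2898	101.9748
K	0.4115	1.4031	2.2784	2.6742	2.2162	0.3703	3.3874	13.1029	68.9592	194.4329
Ca	0.4054	1.3880	2.1602	3.7532	2.2063	0.3499	3.0991	11.9608	53.9353	142.3892
Mn	0.3796	1.2094	1.7815	2.5420	1.5937	0.2699	2.0455	7.4726	31.0604	91.5622
Fe	0.3946	1.2725	1.7031	2.3140	1.4795	0.2717	2.0443	7.6007	29.9714	86.2265
Co	0.4118	1.3161	1.6493	2.1930	1.2830	0.2742	2.0372	7.7205	29.9680	84.9383
Ni	0.3860	1.1765	1.5451	2.0730	1.3814	0.2478	1.7660	6.3107	25.2204	74.3146
Cu	0.4314	1.3208	1.5236	1.4671	0.8562	0.2694	1.9223	7.3474	28.9892	90.6246
Zn	0.4288	1.2646	1.4472	1.8294	1.0934	0.2593	1.7998	6.7500	25.5860	73.5284
Se	0.4477	1.1678	1.5843	2.8087	1.1956	0.2405	1.5442	6.3231	19.4610	52.0233
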