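level	label	numerator	numerator_beta	numerator_p	denominator	denominator_beta	denominator_p	ratio_beta	ratio_p	printed_p_gain	cmp
class	Total PE Ether/PE	Total PE Ether	-0.003	0.00105	PE	0.01	3.36e-35	-0.006	7.39e-13	1.0	lt
class	Total PC Ether/PC	Total PC Ether	-0.015	7.78e-75	PC	0.005	1.38e-09	-0.015	3.94e-77	198.0	eq
class	PE(P)/PE	PE(P)	-0.002	0.00305	PE	0.01	3.36e-35	-0.01	4.41e-39	7600.0	eq
class	PE(O)/PE	PE(O)	-0.008	4.31e-22	PE	0.01	3.36e-35	-0.014	4.3e-68	7.8e+32	eq
class	PC(P)/PC	PC(P)	-0.015	3.48e-78	PC	0.005	1.38e-09	-0.02	1.09e-133	3.2e+55	eq
class	PC(O)/PC	PC(O)	-0.011	1.48e-45	PC	0.005	1.38e-09	-0.014	4.21e-73	3.5e+27	eq
class	TG(O)/TG	TG(O)	0.013	3.08e-63	TG	0.028	4.59e-290	-0.015	6.07e-82	1.0	lt
class	PE(O)/PE(P)	PE(O)	-0.008	4.31e-22	PE(P)	-0.002	0.00305	-0.008	1.29e-25	3340.0	eq
class	PC(P)/PE(P)	PC(P)	-0.015	3.48e-78	PE(P)	-0.002	0.00305	-0.013	3.21e-59	1.0	lt
class	LPE(P)/PE(P)	LPE(P)	-0.005	7.78e-12	PE(P)	-0.002	0.00305	-0.004	9.61e-06	1.0	lt
class	LPC(P)/PC(P)	LPC(P)	-0.014	1.46e-66	PC(P)	-0.015	3.48e-78	-0.001	0.322	1.0	lt
class	LPE/PE	LPE	-0.009	3.98e-28	PE	0.01	3.36e-35	-0.018	2.38e-123	1.41e+88	eq
class	LPC/PC	LPC	-0.007	2.62e-16	PC	0.005	1.38e-09	-0.01	2.25e-37	1.17e+21	eq
species	PE(P-16:0/18:3) [n-3]/PE(P-16:0/20:5) [n-3]	PE(P-16:0/18:3) [n-3]	-0.003	0.000765	PE(P-16:0/20:5) [n-3]	0.001	0.0826	-0.004	3.04e-06	252.0	eq
species	PE(P-18:0/18:3) [n-3]/PE(P-18:0/20:5) [n-3]	PE(P-18:0/18:3) [n-3]	-0.01	1.59e-34	PE(P-18:0/20:5) [n-3]	-0.005	5.82e-09	-0.002	0.00815	1.0	lt
species	PE(P-16:0/20:5) [n-3]/PE(P-16:0/22:5) [n-3]	PE(P-16:0/20:5) [n-3]	0.001	0.0826	PE(P-16:0/22:5) [n-3]	0.003	0.00161	-0.0001	0.93	1.0	lt
species	PE(P-18:0/20:5) [n-3]/PE(P-18:0/22:5) [n-3]	PE(P-18:0/20:5) [n-3]	-0.005	5.82e-09	PE(P-18:0/22:5) [n-3]	-0.002	0.00415	-0.004	7.73e-07	1.0	lt
species	PE(P-16:0/22:5) [n-3]/PE(P-16:0/22:6) [n-3]	PE(P-16:0/22:5) [n-3]	0.003	0.00161	PE(P-16:0/22:6) [n-3]	0.0	0.968	0.002	0.00443	1.0	lt
species	PE(P-18:0/22:5) [n-3]/PE(P-18:0/22:6) [n-3]	PE(P-18:0/22:5) [n-3]	-0.002	0.00415	PE(P-18:0/22:6) [n-3]	-0.009	1.59e-31	0.006	1.99e-16	1.0	lt
species	PE(P-16:0/18:2) [n-6]/PE(P-16:0/20:4) [n-6]	PE(P-16:0/18:2) [n-6]	-0.004	8.99e-07	PE(P-16:0/20:4) [n-6]	0.006	4.35e-15	-0.012	7.31e-52	5.95e+36	eq
species	PE(P-18:0/18:2) [n-6]/PE(P-18:0/20:4) [n-6]	PE(P-18:0/18:2) [n-6]	-0.01	2.13e-34	PE(P-18:0/20:4) [n-6]	0.0	0.598	-0.011	7.25e-39	29400.0	eq
species	PE(P-16:0/20:4) [n-6]/PE(P-16:0/22:4) [n-6]	PE(P-16:0/20:4) [n-6]	0.006	4.35e-15	PE(P-16:0/22:4) [n-6]	0.004	6.24e-08	0.004	4.86e-07	1.0	lt
species	PE(P-18:0/20:4) [n-6]/PE(P-18:0/22:4) [n-6]	PE(P-18:0/20:4) [n-6]	-0.0004	0.598	PE(P-18:0/22:4) [n-6]	0.001	0.441	-0.001	0.215	2.52	eq
species	PE(P-16:0/22:4) [n-6]/PE(P-16:0/22:5) [n-6]	PE(P-16:0/22:4) [n-6]	0.004	6.24e-08	PE(P-16:0/22:5) [n-6]	-0.002	0.0205	0.006	4.15e-15	15000000.0	eq
species	PE(P-18:0/22:4) [n-6]/PE(P-18:0/22:5) [n-6]	PE(P-18:0/22:4) [n-6]	0.001	0.441	PE(P-18:0/22:5) [n-6]	-0.007	2.5e-16	0.008	3.92e-26	6370000000.0	eq
species	PE(P-16:0/18:2)/PE(P-18:0/18:2)	PE(P-16:0/18:2)	-0.004	8.99e-07	PE(P-18:0/18:2)	-0.01	2.13e-34	0.013	2.81e-61	7.58e+26	eq
species	PE(P-16:0/20:4)/PE(P-18:0/20:4)	PE(P-16:0/20:4)	0.006	4.35e-15	PE(P-18:0/20:4)	0.0	0.598	0.012	1.32e-53	3.28e+38	eq
species	PE(P-16:0/22:4)/PE(P-18:0/22:4)	PE(P-16:0/22:4)	0.004	6.24e-08	PE(P-18:0/22:4)	0.001	0.441	0.006	6.8e-13	91800.0	eq
species	PE(P-16:0/22:6)/PE(P-18:0/22:6)	PE(P-16:0/22:6)	0.0	0.968	PE(P-18:0/22:6)	-0.009	1.59e-31	0.017	4.8e-105	3.32e+73	eq
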