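# 10 frozen pure-noise spectra (offset 1 + N(0, 0.1)) on the default grid
# generated once with oximetric.gen_noise_spectra(10, NoiseSpec(0.1, 20200422))
wavelength_nm	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
740	0.968099213115	1.02268283973	0.977609951394	1.06999349896	0.824857755495	1.00399847937	1.16452055417	0.937206601635	1.03271378787	0.930727975806
760	0.956225492259	1.1054121975	1.12403583493	1.0687716629	1.10038730452	1.11577899159	1.06862076918	0.981382407274	1.11193422203	0.99270412386
780	0.917686572121	0.934930022561	1.05833614656	0.91372965284	1.20651188463	0.900880320958	0.979052915651	0.970050076292	1.06730542344	0.930181816679
800	1.1570559633	0.906426219715	1.04581770855	0.965964638957	1.04082466648	0.64398801735	0.822027247255	0.9050457367	1.11865637793	0.907995890013
830	1.05404739092	0.992535794973	0.931229834626	1.0055122909	1.00602977842	1.00558881409	1.18624643316	1.03470809875	0.984367657679	1.16331609131
860	0.950834035604	0.978882992987	1.11345028853	1.07755584817	1.05411141465	0.971505750747	0.90205119349	0.962782437351	0.838436198032	0.849998125932
890	0.859343333742	1.07725271583	1.06831163921	1.00307657145	0.994426477642	1.0721838503	1.19486212643	1.20624920141	1.0795337593	0.932471536288
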