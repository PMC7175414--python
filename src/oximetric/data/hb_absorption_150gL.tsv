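# Whole-blood absorption coefficients of fully oxygenated (HbO2) and fully
# deoxygenated (Hb) blood in the NIR window, derived from the standard
# tabulated molar extinction compilation of human hemoglobin
# (Gratzer/Kollias values, widely reproduced; 10 nm spacing).
# Conversion: mu_a[mm^-1] = ln(10) * eps[cm^-1/M] * (C_THb / MW_Hb) / 10
#   C_THb  = 150 g/L   (assumed total hemoglobin concentration)
#   MW_Hb  = 64500 g/mol
# Columns: wavelength_nm	mu_a_hbo2_per_mm	mu_a_hb_per_mm
700	0.155291	0.960810
710	0.169642	0.813402
720	0.184207	0.685956
730	0.208839	0.590211
740	0.238826	0.597537
750	0.277381	0.752485
760	0.313794	0.829209
770	0.348065	0.702492
780	0.380194	0.575882
790	0.404827	0.477117
800	0.436956	0.407890
810	0.462659	0.383986
820	0.490504	0.371498
830	0.521562	0.371112
840	0.547266	0.370748
850	0.566543	0.370191
860	0.584750	0.370534
870	0.604027	0.374839
880	0.641511	0.388998
890	0.659717	0.398187
900	0.681137	0.407954
910	0.704698	0.417678
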