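# Effective-threshold amplitudes for the spindle-state presets
# (V_reset = -48 mV TC / -42 mV RE), produced by this packages
# own two-stage fitting pipeline (default grid, 5 s per point,
# reps=10, seed=7).  Regenerate with: thalmf make-fixtures
cell	P0	Pmu	Psig	Ptau	Pmumu	Pmusig	Pmutau	Psigsig	Psigtau	Ptautau
TC	-49.117649	8.297030	-30.370598	6.761478	-5.893376	25.794662	-30.687107	11.611287	48.867528	-8.154222
RE	-47.916843	-12.479954	45.873936	-191.812809	6.180805	-0.000564	31.411098	141.030184	-399.505139	558.341184
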