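# Age-banded breast-cancer incidence (h1) and competing (non-breast-cancer) mortality (h2)
# hazards per person-year for the "White" reference population, with the attributable-risk
# complement (1-AR) used by the Gail-type absolute-risk projection (<50 vs >=50 regimes).
# Transcribed from published SEER-era rates underlying standard BCRAT-type implementations;
# representative transcription for research use -- substitute authoritative tables for
# clinical work.
population	age_start	age_end	h1	h2	one_minus_AR
White	20	25	0.0000122	0.0004412	0.5788413
White	25	30	0.0000741	0.0005254	0.5788413
White	30	35	0.0002297	0.0006746	0.5788413
White	35	40	0.0005661	0.0009092	0.5788413
White	40	45	0.0011663	0.0012534	0.5788413
White	45	50	0.0019115	0.0018571	0.5788413
White	50	55	0.0022422	0.0028991	0.5788413
White	55	60	0.0024810	0.0046241	0.5788413
White	60	65	0.0029222	0.0073040	0.5788413
White	65	70	0.0033006	0.0111446	0.5788413
White	70	75	0.0038325	0.0170364	0.5788413
White	75	80	0.0041604	0.0267218	0.5788413
White	80	85	0.0046381	0.0433236	0.5788413
White	85	90	0.0046179	0.0726418	0.5788413
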