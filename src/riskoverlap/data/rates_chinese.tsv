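# Age-banded breast-cancer incidence (h1) and competing mortality (h2) hazards per
# person-year for the "Chinese" population, with attributable-risk complements from the
# Asian-American model extension (<50 vs >=50 regimes). Representative transcription of
# published US Chinese-American rates for research use -- substitute authoritative tables
# for clinical work.
population	age_start	age_end	h1	h2	one_minus_AR
Chinese	20	25	0.0000041	0.0002106	0.4751981
Chinese	25	30	0.0000459	0.0001926	0.4751981
Chinese	30	35	0.0001883	0.0002444	0.4751981
Chinese	35	40	0.0004929	0.0003179	0.4751981
Chinese	40	45	0.0009136	0.0004733	0.4751981
Chinese	45	50	0.0014715	0.0008003	0.4751981
Chinese	50	55	0.0014213	0.0012175	0.5031640
Chinese	55	60	0.0019709	0.0020998	0.5031640
Chinese	60	65	0.0016747	0.0034369	0.5031640
Chinese	65	70	0.0018216	0.0060974	0.5031640
Chinese	70	75	0.0018345	0.0106645	0.5031640
Chinese	75	80	0.0019199	0.0201487	0.5031640
Chinese	80	85	0.0022334	0.0379908	0.5031640
Chinese	85	90	0.0022473	0.0983339	0.5031640
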