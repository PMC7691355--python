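# First-round counts of the Finnish population-based PSA screening trial
# (20,687 evaluable men; inter-screen interval 4 years; cases are
# screen-detected cancers plus interval cancers within 4 years).
# Provenance: all stratum totals are published values, except the
# screen-detected split within 3.0-3.9 ng/ml (23 / 13), which is derived
# from the published sensitivity of 89.3% at cutoff 3.5 ng/ml (= 637/713).
psa_low,psa_high,n_participants,screen_detected,interval_cancers
0.0,1.0,9614,0,5
1.0,2.0,6112,0,17
2.0,2.5,1342,0,7
2.5,3.0,822,0,11
3.0,3.5,623,23,13
3.5,4.0,441,13,9
4.0,inf,1733,548,67
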