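gene	hazard_ratio	ci_low	ci_high	p_value
YTHDC2	0.945573	0.804418	1.111497	0.501143
METTL14	0.87198	0.759141	1.001591	0.057076
IGF2BP1	1.102124	0.987532	1.230014	0.095858
RBM15	1.165283	0.893101	1.520415	0.256693
RBM15B	0.895478	0.794545	1.009233	0.06895
ELAVL1	0.745107	0.585853	0.947651	0.020395
YTHDC1	1.034719	0.880397	1.21609	0.677174
ALKBH5	0.755901	0.631814	0.904358	0.002477
FMR1	1.111698	0.934534	1.322447	0.222155
CBLL1	0.943543	0.786501	1.131941	0.534774
ZC3H13	0.992526	0.822421	1.197816	0.937711
LRPPRC	1.066698	0.898443	1.266463	0.456897
FTO	0.938485	0.838581	1.050291	0.276089
WTAP	0.984003	0.784578	1.234117	0.889144
YTHDF1	0.882007	0.721275	1.078557	0.229438
KIAA1429	1.326562	1.066612	1.649864	0.010711
METTL3	0.820477	0.65659	1.025272	0.083879
YTHDF3	1.087143	0.909575	1.299375	0.351575
YTHDF2	0.988164	0.777414	1.256047	0.922555
HNRNPC	1.147295	0.943431	1.395212	0.155486
HNRNPA2B1	1.129765	0.946279	1.348829	0.166181
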