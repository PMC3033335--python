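# synthetic default core branch-point matrix (CTAAC-like consensus, branch A at position 4)
base	1	2	3	4	5
A	0.10	0.08	0.60	0.94	0.07
C	0.45	0.10	0.05	0.02	0.60
G	0.10	0.06	0.25	0.02	0.08
T	0.35	0.76	0.10	0.02	0.25
background	0.25	0.25	0.25	0.25	0.25
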