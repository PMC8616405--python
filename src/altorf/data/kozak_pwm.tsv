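position	A	C	G	T
-6	0.30	0.35	0.20	0.15
-5	0.50	0.20	0.15	0.15
-4	0.55	0.15	0.15	0.15
-3	0.60	0.20	0.10	0.10
-2	0.45	0.30	0.10	0.15
-1	0.25	0.40	0.15	0.20
4	0.30	0.15	0.40	0.15
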