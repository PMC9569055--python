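id	d1	d2	d3	d4
d1	1.0	0.16666666666666666	0.11538461538461539	0.00033546262790251185
d2	0.16666666666666666	1.0	0.5584901031740597	0.00033546262790251185
d3	0.11538461538461539	0.5584901031740597	1.0	0.01831563888873418
d4	0.00033546262790251185	0.00033546262790251185	0.01831563888873418	1.0
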