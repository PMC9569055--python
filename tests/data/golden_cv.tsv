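id	c1	c2	c3	c4	c5
c1	1.0	0.8333333333333334	0.4305555555555556	0.5952380952380952	0.001661557273173934
c2	0.8333333333333334	1.0	0.4583333333333333	0.5119047619047619	0.00822974704902003
c3	0.4305555555555556	0.4583333333333333	1.0	0.2857142857142857	0.04076220397836621
c4	0.5952380952380952	0.5119047619047619	0.2857142857142857	1.0	0.20189651799465538
c5	0.001661557273173934	0.00822974704902003	0.04076220397836621	0.20189651799465538	1.0
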