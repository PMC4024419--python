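pair_name	forward_name	forward_seq	reverse_name	reverse_seq	annealing_c	expected_wt_bp	expected_mut_bp
XPV10	XPV10F	CCTGGTTCTTTTAATTTCCTCTCCTG	XPV10R	CATTTACCCTTTACCTCATTGAAGGAC	55	459
XPVdel10	XPVdel10F	TCATTTGTGCTGTCCTGTTC	XPVdel10R	GGTTGCAGTGAGCGGAGATT	60	3012
Delex10LR	Delex10LR-F	AGGTCCTCCCTAGTTACCCTATCACAGCAG	Delex10LR-R	ACTACCTAACCCTGACTGACTTACCACTCTGG	60	4105
POLH10d	POLH10dF	AGTGGGTAGGTTTTGGTAGCTGTGGAAG	POLH10dR	GGACACACCCTGGATACTCTGTTGGTAA	60	9358	~6000
POLHd	POLHFd	ACCTTGGAGTATAATTTCTGGGTCA	POLHRd	GTCATAAAGTTCCTCATTGTGTCTAA	59	5212	~1000
POLHdel	POLHdelF	CATGTGCTTGTTGGACATTTG	POLHdelR	GGTTTCATGCTTTGGGACAG	60	4526	~500
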