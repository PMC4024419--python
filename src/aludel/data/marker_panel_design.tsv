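# Marker panel as named in the study design: a 0.4 Mb interval around the
# POLH locus, centromeric D6S207 and telomeric D6S1582.
marker	map_position	side
D6S207	1	cen
D6S1582	2	tel
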