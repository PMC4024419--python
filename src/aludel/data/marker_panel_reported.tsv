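# Marker panel as named in the reported haplotype results: the two markers
# closest to the POLH locus, D6S1582 and D6S271 (founder haplotype 129-188).
# Both this and marker_panel_design.tsv ship because the two namings differ;
# the panel is user-defined and the discrepancy is documented, not resolved.
marker	map_position	side
D6S1582	1	cen
D6S271	2	tel
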