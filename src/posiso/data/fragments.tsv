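# Default fragment library: TMS/MEOX-derivatized metabolite ions monitored by
# GC-EI-(TOF)MS (radical dissociation from [M]+) and GC-APCI-(TOF)MS (neutral
# elimination from [M+H]+). retained_positions are parent-metabolite carbon
# positions; n_derivatization_carbons counts TMS/MEOX carbons (never labeled).
id	formula	instrument_mode	retained_positions	n_derivatization_carbons	note
3PGA_459	C14H36O7PSi4+	EI	1,2,3	11	3PGA(4TMS) [M-CH3]+; all three 3PGA carbons
3PGA_459	C14H36O7PSi4+	APCI	1,2,3	11	3PGA(4TMS) [M+H-CH4]+; all three 3PGA carbons
3PGA_357	C11H30O5PSi3+	EI	2,3	9	3PGA(4TMS) [M-TMSCOO]+; 2,3-C2 after loss of 1-C
3PGA_357	C11H30O5PSi3+	APCI	2,3	9	3PGA(4TMS) [M+H-TMSCOOH]+; 2,3-C2 after loss of 1-C
G6P_706	C24H61NO9PSi6+	APCI	1,2,3,4,5,6	18	G6P(1MEOX)(6TMS) [M+H-CH4]+; complete hexose backbone
3PGA_315	C9H28O4PSi3+	EI	-	9	protonated tris-TMS phosphate qualifier; no labelable C (synthetic qualifier formula at nominal mass 315)
3PGA_299	C8H24O4PSi3+	EI	-	8	phosphate-moiety qualifier, 315-CH4; no labelable C (synthetic qualifier formula at nominal mass 299)
sorbitol_599	C23H59O6Si6+	APCI	1,2,3,4,5,6	17	sorbitol(6TMS) [M+H-CH4]+; internal-standard channel (13C6-sorbitol)
glucose_554	C21H52NO6Si5+	APCI	1,2,3,4,5,6	15	glucose(1MEOX)(5TMS) [M+H-CH4]+
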