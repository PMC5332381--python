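# Curated GRAS gene counts per orthogroup in eight angiosperm species.
# Cell grammar: integer, integer followed by "*" (remnant copy detectable
# in the genome), or "-" (no member found).
#outgroup_specific	NSP2-Amb
og	Amb	Ma	Pd	Os	Vv	Tc	At	Cc
OG-SCR-1	1	3	2	2	1	1	1	1
OG-SCR-2	2	1	2	1	1	1	1	1*
OG-SCR-3	1	-	1	1*	1	1	-	1
OG-SHR-1	1	3	2	2	1	1	1	1
OG-SHR-2	1	3	2	-	1	1	-	1
OG-SCL32-1	1	3	2	1	1	1	1*	1
OG-SCL32-2	1	1	1	1	1	1	-	2
OG-NSP1	1	1	2	1*	1	1	1	1
OG-LS	1*	4	4	2*	1	1	1	1
OG-SCL4/7	1	3	2	1	1	1	2	1
OG-NSP2-1	1	1	2	1	1	1	1	1
OG-NSP2-2	1	-	1	2	1	-	-	1*
OG-NSP2-3	1	-	-	-	3	2	-	2
NSP2-Amb	2	-	-	-	-	-	-	-
OG-HAM-II	1	7	4	5	2	2	3	2
OG-HAM-I	1	3	2	-	1	1	1	1
OG-DELLA-1	1*	4*	2	1	2	2*	5	2*
OG-DELLA-2	1	1	2	2	1	1	-	1
OG-PAT-1	1	3	2	3	3	3	4	2
OG-PAT-2	1	4	2	1	1*	1	-	1
OG-PAT-3	1	3	1	1	2	1	1	1
OG-PAT-4	-	7*	2	2*	1	1	1	1
OG-SCL3	1	3	3	9*	3*	3	1	2
OG-RAD1-1	1	1	1	1*	2	2	-	2
OG-RAD1-2	1	-	1	-	1	1	-	-
OG-RAM1	1*	1	1	1	1	1	-	1
OG-DLT	1	3*	2	1*	1	1	1	1
OG-SCLA	1	2	2	1	1	1	-	2
OG-SCLB	4*	-	5	-	1*	3	-	5*
OG-LISCL	1	7	4	13*	11*	7	7	11*
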