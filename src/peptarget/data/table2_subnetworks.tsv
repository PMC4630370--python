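term	go_id	nodes	targets	s_net
Insulin receptor signaling pathway	GO:0008286	57	15	0.175
Positive regulation of biosynthetic process	GO:0009891	73	19	0.173
Positive regulation of NF-kappaB transcription factor activity	GO:0051092	40	14	0.165
Protein autoprocessing	GO:0016540	67	14	0.165
Extracellular structure organization	GO:0043062	66	13	0.143
Mitochondrion organization	GO:0007005	68	17	0.136
Antiapoptosis	GO:0006916	178	26	0.112
Interleukin-6 production	GO:0032635	21	8	0.105
Response to hypoxia	GO:0001666	68	14	0.103
Negative regulation of cell cycle	GO:0045786	37	8	0.076
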