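protein_id	gene	CBP	FLAG	HIS	S
18999	Pou5f1	2.0	7.0	12.0	Exc
12534	Cdk1	0.7	0.7	Exc	Exc
14211	Smc2	0.8	Exc	Exc	
19360	Rad50	Exc	Exc	1.3	
69912	Nup43	Exc	Exc	1.2	
14897	Trip12	9.0	Exc	0.5	
104721	Ddx1	0.5	Exc	Exc	
13204	Dhx15	0.6	3.0	22.5	
67134	Nop56		Exc		Exc
16647	Kpna2	Exc	Exc		
71805	Nup93	1.6	4.0	Exc	
445007	Nup85	3.5	Exc		
55989	Nop58	1.8	Exc		Exc
103468	Nup107	3.3	Exc	0.8	
100088	Rcc1	Exc	3.0		
21681	Thoc4		Exc		Exc
98386	Lbr		Exc	3.5	
218210	Nup153	Exc	Exc		
170762	Nup155	9.5	3.6	0.9	
21873	Tjp2	2.0	Exc	0.5	Exc
103573	Xpo1	3.0	Exc		
20624	Eftud2	0.5	4.3	0.8	Exc
22185	U2af2		Exc		Exc
56403	Syncrip		5.0		3.0
72584	Cul4b	Exc	Exc		
20163	Rsu1	Exc		Exc	
83797	Smarcd1	1.0	6.0	1.0	Exc
320267	Fubp3	3.3	4.0		Exc
233908	Fus	Exc			Exc
75273	Pelp1	Exc	Exc	0.6	
101739	Psip1	2.5	Exc		4.0
230908	Tardbp	0.6	5.0	Exc	2.0
21973	Top2a	3.7	1.8	0.7	4.0
140486	Igf2bp1		Exc		Exc
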