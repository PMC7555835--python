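set	clade_target	name	orientation	sequence	start	end
comaA	cladeA	comaA-244f_a	forward	TACAACTGGGTGAACTA	244	260
comaA	cladeA	comaA-244f_b	forward	TATAACTGGGTGAACTA	244	260
comaA	cladeA	comaA-244f_c	forward	TACAATTGGGTGAACTA	244	260
comaA	cladeA	comaA-244f_d	forward	TACAACTGGGTCAACTA	244	260
comaA	cladeA	comaA-244f_e	forward	TACAACTGGGTCAATTA	244	260
comaA	cladeA	comaA-244f_f	forward	TATAACTGGGTCAATTA	244	260
comaA	cladeA	comaA-659r_a	reverse	AGATCATGGTGCTATG	644	659
comaA	cladeA	comaA-659r_b	reverse	AAATCATGGTGCTATG	644	659
comaA	cladeA	comaA-659r_c	reverse	AGATCATGGTGCTGTG	644	659
comaA	cladeA	comaA-659r_d	reverse	AAATCATGGTGCTGTG	644	659
comaA	cladeA	comaA-659r_e	reverse	AGATCATCGTGCTGTG	644	659
comaA	cladeA	comaA-659r_f	reverse	AAATCATCGTGCTGTG	644	659
comaB	cladeB	comaB-244f_a	forward	TAYTTCTGGACGTTCTA	244	260
comaB	cladeB	comaB-244f_b	forward	TAYTTCTGGACATTCTA	244	260
comaB	cladeB	comaB-244f_c	forward	TACTTCTGGACTTTCTA	244	260
comaB	cladeB	comaB-244f_d	forward	TAYTTCTGGACGTTTTA	244	260
comaB	cladeB	comaB-244f_e	forward	TAYTTCTGGACATTTTA	244	260
comaB	cladeB	comaB-244f_f	forward	TACTTCTGGACCTTCTA	244	260
comaB	cladeB	comaB-659r_a	reverse	ARATCCAGACGGTGTG	644	659
comaB	cladeB	comaB-659r_b	reverse	ARATCCAAACGGTGTG	644	659
comaB	cladeB	comaB-659r_c	reverse	ARATCCAGACAGTGTG	644	659
comaB	cladeB	comaB-659r_d	reverse	ARATCCAAACAGTGTG	644	659
comaB	cladeB	comaB-659r_e	reverse	AGATCCAGACTGTGTG	644	659
comaB	cladeB	comaB-659r_f	reverse	AGATCCAAACAGTGTG	644	659
Ntsp	total	Ntsp-amoA-162F	forward	GGATTTCTGGNTSGATTGGA	162	181
Ntsp	total	Ntsp-amoA-359R	reverse	WAGTTNGACCACCASTACCA	340	359
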