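Sample ID	Birthplace	64	73	194	195	228	249	263	290	291	310i	315i	350	7697	16051	16092	16129	16140	16172	16188	16192	16209	16221	16223	16259	16266	16271	16287	16288	16298	16311	16325	16327
rCRS		C	A	C	T	G	A	A	A	A	-	-	A	G	A	T	G	T	T	C	C	T	C	C	C	C	T	C	T	T	T	T	C
KC004	Montevideo, Uruguay	.	G	T	.	.	d	G	d	d	.	C	.	A	G	.	.	.	.	.	.	.	.	T	.	.	.	T	.	C	C	C	T
KC018	Montevideo, Uruguay	.	G	T	.	.	d	G	d	d	.	C	.	.	G	.	.	C	.	.	.	C	.	T	.	.	.	.	C	C	.	C	T
KC043	Montevideo, Uruguay	.	G	T	C	.	d	G	d	d	C	C	G	A	G	.	.	.	.	.	.	.	.	T	T	.	C	.	.	C	C	C	T
KC049	Buenos Aires, Argentina													A	G	.	.	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
KC150	Mercedes, Uruguay	.	G	T	C	.	d	G	d	d	C	C	.	A	G	.	.	.	.	.	.	.	.	T	.	T	.	.	.	C	.	C	T
KC161	Constitución, Uruguay	T	G	T	.	.	d	G	d	d	.	C	.	A	G	.	.	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
KC163	Tupambaé, Uruguay	T	G	T	C	.	d	G	d	d	C	C	.	A	G	.	.	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
KC208	Rocha, Uruguay	.	G	T	.	.	d	G	d	d	.	C	.	.	G	.	.	C	.	.	.	.	.	T	.	.	.	.	C	C	.	C	T
KP040	Canelones, Uruguay													A	G	.	.	.	.	.	T	.	T	T	.	.	.	.	.	C	.	C	T
KP053	Canelones, Uruguay													A	G	.	.	.	.	T	.	.	.	T	.	.	.	.	.	C	.	C	T
KP055	Montevideo, Uruguay													A	G	.	A	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
KP079	Montevideo, Uruguay													A	G	.	.	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
KP108	Chuy, Uruguay													A	G	.	.	.	C	.	.	.	.	T	.	.	.	.	.	C	.	C	T
B11	Trinidad, Uruguay		G	T	.	.	d	G	d	d	.	C	.	.	G	.	.	C	.	.	.	.	.	T	.	.	.	.	C	C	.	C	T
UryAr010	Artigas, Uruguay		G	T	C	A	d	G	d	d	.	C	.		G	C	.	.	.	.	.	.	.	T	.	.	.	.	.	C	.	C	T
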