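# Curated cloverleaf annotation for human mt-tRNA-Leu(UUR), rCRS m.3230-3304 (75 nt, heavy strand).
# Domain boundaries follow canonical mammalian mt-tRNA cloverleaf
# geometry and are approximate at single-position resolution.
position	domain	partner
1	acceptor_stem	74
2	acceptor_stem	73
3	acceptor_stem	72
4	acceptor_stem	71
5	acceptor_stem	70
6	acceptor_stem	69
7	acceptor_stem	68
8	other	.
9	other	.
10	d_stem	25
11	d_stem	24
12	d_stem	23
13	d_stem	22
14	d_loop	.
15	d_loop	.
16	d_loop	.
17	d_loop	.
18	d_loop	.
19	d_loop	.
20	d_loop	.
21	d_loop	.
22	d_stem	13
23	d_stem	12
24	d_stem	11
25	d_stem	10
26	other	.
27	anticodon_stem	43
28	anticodon_stem	42
29	anticodon_stem	41
30	anticodon_stem	40
31	anticodon_stem	39
32	anticodon_loop	.
33	anticodon_loop	.
34	anticodon_loop	.
35	anticodon_loop	.
36	anticodon_loop	.
37	anticodon_loop	.
38	anticodon_loop	.
39	anticodon_stem	31
40	anticodon_stem	30
41	anticodon_stem	29
42	anticodon_stem	28
43	anticodon_stem	27
44	variable_region	.
45	variable_region	.
46	variable_region	.
47	variable_region	.
48	variable_region	.
49	t_stem	65
50	t_stem	64
51	t_stem	63
52	t_stem	62
53	t_stem	61
54	t_loop	.
55	t_loop	.
56	t_loop	.
57	t_loop	.
58	t_loop	.
59	t_loop	.
60	t_loop	.
61	t_stem	53
62	t_stem	52
63	t_stem	51
64	t_stem	50
65	t_stem	49
66	other	.
67	other	.
68	acceptor_stem	7
69	acceptor_stem	6
70	acceptor_stem	5
71	acceptor_stem	4
72	acceptor_stem	3
73	acceptor_stem	2
74	acceptor_stem	1
75	other	.
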