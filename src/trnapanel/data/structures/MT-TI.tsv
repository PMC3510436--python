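# Curated cloverleaf annotation for human mt-tRNA-Ile, rCRS m.4263-4331 (69 nt, heavy strand).
# Domain boundaries follow canonical mammalian mt-tRNA cloverleaf
# geometry and are approximate at single-position resolution.
position	domain	partner
1	acceptor_stem	69
2	acceptor_stem	68
3	acceptor_stem	67
4	acceptor_stem	66
5	acceptor_stem	65
6	acceptor_stem	64
7	acceptor_stem	63
8	other	.
9	other	.
10	d_stem	24
11	d_stem	23
12	d_stem	22
13	d_stem	21
14	d_loop	.
15	d_loop	.
16	d_loop	.
17	d_loop	.
18	d_loop	.
19	d_loop	.
20	d_loop	.
21	d_stem	13
22	d_stem	12
23	d_stem	11
24	d_stem	10
25	other	.
26	anticodon_stem	42
27	anticodon_stem	41
28	anticodon_stem	40
29	anticodon_stem	39
30	anticodon_stem	38
31	anticodon_loop	.
32	anticodon_loop	.
33	anticodon_loop	.
34	anticodon_loop	.
35	anticodon_loop	.
36	anticodon_loop	.
37	anticodon_loop	.
38	anticodon_stem	30
39	anticodon_stem	29
40	anticodon_stem	28
41	anticodon_stem	27
42	anticodon_stem	26
43	variable_region	.
44	variable_region	.
45	variable_region	.
46	variable_region	.
47	t_stem	62
48	t_stem	61
49	t_stem	60
50	t_stem	59
51	t_stem	58
52	t_loop	.
53	t_loop	.
54	t_loop	.
55	t_loop	.
56	t_loop	.
57	t_loop	.
58	t_stem	51
59	t_stem	50
60	t_stem	49
61	t_stem	48
62	t_stem	47
63	acceptor_stem	7
64	acceptor_stem	6
65	acceptor_stem	5
66	acceptor_stem	4
67	acceptor_stem	3
68	acceptor_stem	2
69	acceptor_stem	1
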