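# Clinical characteristics of the 24 enrolled familial Crohn's disease
# patients (12 families), Montreal-coded. Duration "<1" denotes under one
# year and is kept as an interval, not a number.
patient_id	family_id	kinship	age	sex	duration	location	behavior	pelvic_disease	abdominal_surgery
F1-II-1	F1	fraternal twins	18	male	5	L3	B3	yes	yes
F1-II-2	F1	fraternal twins	18	male	3	L3	B3	yes	no
F2-II-1	F2	fraternal twins	22	female	7	L3+L4	B1	yes	no
F2-II-2	F2	fraternal twins	22	female	8	L3+L4	B1	yes	no
F3-I-3	F3	aunt and nephew	42	female	1	L3	B3	no	yes
F3-II-1	F3	aunt and nephew	19	male	<1	L3	B1	yes	no
F4-I-2	F4	mother and daughter	45	female	10	L3	B3	yes	yes
F4-II-2	F4	mother and daughter	24	female	5	L3	B2	no	no
F5-I-1	F5	father and son	44	male	18	L3	B2	no	yes
F5-II-1	F5	father and son	21	male	<1	L3	B1	yes	no
F6-II-1	F6	identical twins	14	female	<1	L3	B2	no	no
F6-II-2	F6	identical twins	14	female	<1	L2	B2	yes	no
F7-II-1	F7	elder sister and younger brother	23	female	2	L3	B1	no	no
F7-II-2	F7	elder sister and younger brother	21	male	1	L3	B3	no	no
F8-I-1	F8	father and son	44	male	2	L1+L4	B2	yes	no
F8-II-1	F8	father and son	20	male	6	L1+L4	B3	yes	no
F9-II-1	F9	elder and younger brother	31	male	1	L3+L4	B1	yes	no
F9-II-2	F9	elder and younger brother	26	male	2	L3+L4	B1	yes	no
F10-I-1	F10	father and daughter	45	male	7	L1	B2	no	yes
F10-II-1	F10	father and daughter	14	female	5	L3	B3	no	no
F11-II-1	F11	identical twins	37	male	11	L3	B3	no	yes
F11-II-2	F11	identical twins	37	male	11	L3	B3	no	no
F12-II-1	F12	identical twins	15	female	1	L3	B1	yes	no
F12-II-2	F12	identical twins	15	female	1	L3	B1	no	no
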