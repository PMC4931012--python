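strain_id	species	hmo_growth	GH29	GH95	FL_SBP
BR-06	Bifidobacterium breve	grower	0	1	1
BR-10	Bifidobacterium breve	grower	0	1	1
BR-14	Bifidobacterium breve	grower	0	1	1
BR-15	Bifidobacterium breve	grower	0	1	1
BR-20	Bifidobacterium breve	grower	0	1	1
BR-21	Bifidobacterium breve	grower	0	1	1
BR-A29	Bifidobacterium breve	grower	0	1	1
BR-I29	Bifidobacterium breve	grower	0	1	1
BR-07	Bifidobacterium breve	non_grower	0	1	0
BR-19	Bifidobacterium breve	non_grower	0	1	0
BR-C29	Bifidobacterium breve	non_grower	0	1	0
BR-H29	Bifidobacterium breve	non_grower	0	1	0
BR-L29	Bifidobacterium breve	non_grower	0	1	0
IN-07	Bifidobacterium longum ss. infantis	grower	1	1	1
IN-F29	Bifidobacterium longum ss. infantis	grower	1	1	1
LO-06	Bifidobacterium longum ss. longum	non_grower	0	0	0
LO-10	Bifidobacterium longum ss. longum	non_grower	0	0	0
LO-21	Bifidobacterium longum ss. longum	non_grower	0	0	0
LO-C29	Bifidobacterium longum ss. longum	non_grower	0	0	0
LO-K29a	Bifidobacterium longum ss. longum	non_grower	0	0	0
LO-K29b	Bifidobacterium longum ss. longum	non_grower	0	0	0
CA-C29	Bifidobacterium pseudocatenulatum	grower	0	1	1
CA-K29a	Bifidobacterium pseudocatenulatum	grower	0	1	1
CA-K29b	Bifidobacterium pseudocatenulatum	grower	0	1	1
CA-05	Bifidobacterium pseudocatenulatum	non_grower	0	0	0
CA-B29	Bifidobacterium pseudocatenulatum	non_grower	0	0	0
CA-D29	Bifidobacterium pseudocatenulatum	non_grower	0	0	0
BI-14	Bifidobacterium bifidum	grower	1	1	0
DE-29	Bifidobacterium dentium	non_grower	1	0	0
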