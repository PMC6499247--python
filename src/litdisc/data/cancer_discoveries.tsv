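a_id	b_id	c_id	discovery_year	mode
PR:000001754	PR:000002307	MESH:D000236	2010	both
PR:000011331	HOC:42	PR:000005308	2011	both
PR:000001138	PR:000003107	PR:000006736	2011	both
PR:000011170	CHEBI:26523	MESH:D010190	2013	both
PR:000006066	HOC:42	MESH:D013964	2016	both
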