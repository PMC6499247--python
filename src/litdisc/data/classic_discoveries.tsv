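a_id	b_id	c_id	discovery_year	mode
MESH:D008881	-	MESH:D008274	1988	open
PR:000009182	-	CHEBI:29016	1990	open
MESH:D000544	-	MESH:D004967	1996	open
MESH:D000544	-	MESH:D007213	1996	open
MESH:D012559	-	PR:000012942	1998	open
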