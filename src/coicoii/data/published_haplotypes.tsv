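name	lineage	structure	accession
A1x	A	P0Q	PP667401
A8k	A	P0Q	PP667402
A68	A	P0QQ	PP667403
A69	A	P0QQ	PP667404
A70	A	P0QQ	PP667405
A71a	A	P0QQ	PP667406
A72	A	P0QQ	PP667407
A73	A	P0QQ	PP667408
A70a	A	P0QQ	PP667409
A74a	A	P0QQ	PP667410
A73a	A	P0QQ	PP667411
A74	A	P0QQ	PP667412
A74b	A	P0QQ	PP667413
A75	A	P0QQ	PP667414
A76	A	P0QQ	PP667415
A77′	A	P0QQQ	PP667416
M4r	M	PQQ	PP667417
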