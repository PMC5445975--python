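##gff-version 3
I	test	gene	1100	1600	.	+	.	ID=SPTEST.01;Name=cdc2
I	test	mRNA	1100	1600	.	+	.	ID=SPTEST.01.1;Parent=SPTEST.01
I	test	CDS	1150	1450	.	+	0	ID=SPTEST.01.1:cds;Parent=SPTEST.01.1
II	test	gene	1200	1500	.	-	.	ID=SPNCRNA.01
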