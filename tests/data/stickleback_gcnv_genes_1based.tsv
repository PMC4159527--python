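#gene_id	chrom	start_1based	end_1based
ENSGACG00000014268	groupI	21,543,442	21,565,537
ENSGACG00000014289	groupI	21,600,545	21,614,802
ENSGACG00000018214	groupIV	11,925,723	11,934,224
ENSGACG00000019313	groupIV	23,928,955	23,953,125
ENSGACG00000019321	groupIV	23,968,608	23,982,358
ENSGACG00000020171	groupVII	12,721,951	12,727,083
ENSGACG00000014553	groupXI	15,607,308	15,613,431
ENSGACG00000002886	groupXIX	2,446,925	2,473,806
ENSGACG00000002902	groupXIX	2,484,537	2,497,605
ENSGACG00000002933	groupXIX	2,501,529	2,511,962
ENSGACG00000006397	groupXX	6,176,973	6,190,798
ENSGACG00000002551	groupXXI	5,808,646	5,870,440
ENSGACG00000002682	groupXXI	6,189,464	6,240,135
ENSGACG00000002744	groupXXI	6,534,938	6,558,550
ENSGACG00000002857	groupXXI	7,179,938	7,191,684
ENSGACG00000002913	groupXXI	7,252,896	7,262,425
ENSGACG00000002918	groupXXI	7,255,256	7,257,350
ENSGACG00000003408	groupXXI	7,994,019	7,996,973
ENSGACG00000015099	scaffold_68	405,524	407,382
ENSGACG00000019508	groupIV	25,553,051	25,563,391
ENSGACG00000020238	groupVII	14,778,775	14,788,878
ENSGACG00000003374	groupVIII	1,526,335	1,528,158
ENSGACG00000003379	groupVIII	1,528,722	1,530,746
ENSGACG00000005313	groupXI	1,204,843	1,206,464
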