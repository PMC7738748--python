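##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=Scaffold_1>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	P1	P2
Scaffold_1	108	.	A	G	.	PASS	QD=8;FS=30;MQ=60;MQRankSum=-10.52;ReadPosRankSum=-7.96	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	118	.	A	G	.	PASS	QD=8;FS=0;MQ=35	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	126	.	A	G	.	PASS	QD=2;FS=0;MQ=60;MQRankSum=-9.82;ReadPosRankSum=-1.95	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	134	.	A	G	.	PASS	QD=2;FS=5;MQRankSum=-1.65;ReadPosRankSum=-0.16	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	144	.	A	G	.	PASS	QD=0.5;FS=3;MQ=35;MQRankSum=0.1	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	184	.	A	G	.	PASS	QD=0.5;FS=3;ReadPosRankSum=-2.39	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	224	.	A	G	.	PASS	QD=2;FS=0;MQ=60;MQRankSum=-4.98	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	264	.	A	G	.	PASS	QD=1.9;FS=29.9;MQ=35;MQRankSum=-11.83;ReadPosRankSum=-2.07	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	304	.	A	G	.	PASS	QD=2;FS=30;MQ=40	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	314	.	A	G	.	PASS	QD=0.5;FS=2;MQ=40;ReadPosRankSum=-2.7	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	354	.	A	G	.	PASS	QD=30;FS=3;MQRankSum=1.45;ReadPosRankSum=1.01	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	362	.	A	G	.	PASS	.	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	562	.	A	G	.	PASS	QD=0.5;FS=61;MQRankSum=-9.88;ReadPosRankSum=-0.81	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	574	.	A	G	.	PASS	QD=8;FS=30;MQ=35;MQRankSum=-6.6	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	584	.	A	G	.	PASS	QD=8;FS=2;MQRankSum=-9.72	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	784	.	A	G	.	PASS	QD=25;FS=61;MQRankSum=-11.45	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	794	.	A	G	.	PASS	QD=25;FS=30.1;MQRankSum=-8.22;ReadPosRankSum=-6.31	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	834	.	A	G	.	PASS	QD=18;FS=3;MQ=55;MQRankSum=-5.73;ReadPosRankSum=1.68	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	846	.	A	G	.	PASS	QD=2;FS=2;MQ=35;MQRankSum=-10.1;ReadPosRankSum=-4.46	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	858	.	A	G	.	PASS	QD=0.5;FS=30.1;MQRankSum=-3.14;ReadPosRankSum=-7.37	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	866	.	A	G	.	PASS	QD=30;FS=45;MQ=60;MQRankSum=-5.14	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	878	.	A	G	.	PASS	QD=2;FS=30;MQ=60;MQRankSum=-6.19;ReadPosRankSum=-6.67	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	918	.	A	G	.	PASS	QD=30;FS=61;ReadPosRankSum=-4.73	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	930	.	A	G	.	PASS	QD=2.1;FS=1;MQ=60;MQRankSum=-6.79;ReadPosRankSum=1.13	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	940	.	A	G	.	PASS	QD=25;FS=3;MQ=60;MQRankSum=-6.92;ReadPosRankSum=-0.21	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	955	.	A	G	.	PASS	QD=2.1;FS=5;MQ=60;MQRankSum=-7.24	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1155	.	A	G	.	PASS	QD=30;FS=30;MQ=35	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1355	.	A	G	.	PASS	QD=2.1;FS=3;MQRankSum=-6.33	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1555	.	A	G	.	PASS	QD=25;FS=30.1;MQ=55;MQRankSum=1.34;ReadPosRankSum=0.81	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1595	.	A	G	.	PASS	QD=18;FS=29.9;MQ=35;MQRankSum=0.41;ReadPosRankSum=-2.82	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1795	.	A	G	.	PASS	QD=2;FS=5;MQ=60;MQRankSum=-2.99;ReadPosRankSum=0.11	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1835	.	A	G	.	PASS	QD=18;FS=45;MQRankSum=-12.45;ReadPosRankSum=-4.28	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1875	.	A	G	.	PASS	QD=0.5;FS=29.9;MQ=40;ReadPosRankSum=-6.92	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	1885	.	A	G	.	PASS	QD=25;FS=29.9;MQ=35;MQRankSum=-2.29	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2085	.	A	G	.	PASS	QD=0.5;FS=5;MQ=55	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2285	.	A	G	.	PASS	QD=0.5;FS=2;MQ=35;MQRankSum=-11.53;ReadPosRankSum=0.06	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2295	.	A	G	.	PASS	QD=30;FS=1;MQ=35;MQRankSum=-11.14;ReadPosRankSum=-4.53	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2335	.	A	G	.	PASS	QD=0.5;FS=30.1;MQ=40	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2535	.	A	G	.	PASS	QD=1.9;FS=2;MQ=40;ReadPosRankSum=-2.3	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2545	.	A	G	.	PASS	QD=0.5;FS=5;MQ=40;MQRankSum=-5.69	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2585	.	A	G	.	PASS	QD=25;FS=45;MQ=60;MQRankSum=-3.86	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2597	.	A	G	.	PASS	QD=30;FS=30.1;MQ=55;MQRankSum=-2.89;ReadPosRankSum=-7.26	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2797	.	A	G	.	PASS	QD=2;FS=5;MQ=55;MQRankSum=0.3;ReadPosRankSum=-7.71	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2812	.	A	G	.	PASS	QD=18;FS=2;MQ=40;MQRankSum=-2.73;ReadPosRankSum=-3.02	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2852	.	A	G	.	PASS	.	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2860	.	A	G	.	PASS	QD=30;FS=45;MQ=40;MQRankSum=-6.29	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2875	.	A	G	.	PASS	QD=18;FS=45;MQ=60;ReadPosRankSum=0.2	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2890	.	A	G	.	PASS	QD=0.5;FS=2;MQRankSum=-8.48;ReadPosRankSum=-4.41	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2900	.	A	G	.	PASS	QD=2.1;FS=30.1;MQ=55;MQRankSum=-4.23	GT:AD	0/1:10,12	0/0:20,0
Scaffold_1	2915	.	A	G	.	PASS	QD=0.5;FS=0;MQ=60;MQRankSum=-7.75;ReadPosRankSum=-3.68	GT:AD	0/1:10,12	0/0:20,0
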