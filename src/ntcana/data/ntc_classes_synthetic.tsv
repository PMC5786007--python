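# synthetic NtC class table: constructed canonical-geometry templates,
# not curated experimental statistics
ntc_class	cana	mean_delta	mean_epsilon	mean_zeta	mean_alpha1	mean_beta1	mean_gamma1	mean_delta1	mean_chi	mean_chi1	esd_delta	esd_epsilon	esd_zeta	esd_alpha1	esd_beta1	esd_gamma1	esd_delta1	esd_chi	esd_chi1	mean_P1	mean_P2	esd_P
AA00	AAA	83.0	205.0	287.0	295.0	174.0	52.0	83.0	203.0	203.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	18.0	6.0
AA01	AAA	83.0	220.0	287.0	295.0	163.0	52.0	83.0	203.0	203.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	18.0	6.0
AA02	AAA	83.0	205.0	269.0	295.0	174.0	65.0	83.0	203.0	203.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	18.0	6.0
AA03	AAA	83.0	205.0	287.0	316.0	174.0	52.0	83.0	188.0	203.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	18.0	6.0
AA04	AAA	83.0	205.0	287.0	295.0	150.0	52.0	83.0	203.0	220.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	18.0	6.0
AB01	A-B	85.0	200.0	290.0	298.0	176.0	49.0	140.0	205.0	248.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	150.0	6.0
AB02	A-B	85.0	215.0	290.0	298.0	165.0	49.0	140.0	205.0	248.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	150.0	6.0
AB03	A-B	85.0	200.0	272.0	298.0	176.0	62.0	140.0	205.0	248.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	18.0	150.0	6.0
BA01	B-A	138.0	185.0	263.0	300.0	178.0	48.0	85.0	248.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA05	B-A	138.0	200.0	263.0	300.0	167.0	48.0	85.0	248.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA08	B-A	138.0	185.0	245.0	300.0	178.0	61.0	85.0	248.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA09	B-A	138.0	185.0	263.0	321.0	178.0	48.0	85.0	233.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA10	B-A	138.0	185.0	263.0	300.0	154.0	48.0	85.0	248.0	222.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA13	B-A	138.0	166.0	263.0	300.0	178.0	75.0	85.0	248.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA16	B-A	138.0	185.0	284.0	300.0	178.0	48.0	85.0	218.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BA17	B-A	138.0	185.0	263.0	277.0	178.0	48.0	85.0	248.0	238.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	152.0	18.0	6.0
BB00	BBB	135.0	187.0	262.0	303.0	179.0	45.0	135.0	250.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
BB01	2B1	138.0	183.0	246.0	306.0	168.0	42.0	133.0	253.0	247.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	158.0	152.0	6.0
BB02	3B1	134.0	188.0	262.0	150.0	178.0	182.0	135.0	249.0	251.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	154.0	156.0	6.0
BB03	3B1	134.0	203.0	262.0	150.0	167.0	182.0	135.0	249.0	251.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	154.0	156.0	6.0
BB04	B12	136.0	215.0	225.0	305.0	177.0	44.0	136.0	252.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	156.0	154.0	6.0
BB05	B12	136.0	230.0	225.0	305.0	166.0	44.0	136.0	252.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	156.0	154.0	6.0
BB07	BB2	137.0	250.0	180.0	300.0	176.0	43.0	138.0	255.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	158.0	152.0	6.0
BB08	BB2	137.0	265.0	180.0	300.0	165.0	43.0	138.0	255.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	158.0	152.0	6.0
BB10	miB	140.0	195.0	255.0	295.0	160.0	50.0	130.0	245.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB11	miB	140.0	210.0	255.0	295.0	149.0	50.0	130.0	245.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB12	miB	140.0	195.0	237.0	295.0	160.0	63.0	130.0	245.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB13	miB	140.0	195.0	255.0	316.0	160.0	50.0	130.0	230.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB14	miB	140.0	195.0	255.0	295.0	136.0	50.0	130.0	245.0	272.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB15	miB	140.0	176.0	255.0	295.0	160.0	77.0	130.0	245.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
BB16	miB	140.0	195.0	276.0	295.0	160.0	50.0	130.0	215.0	255.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	160.0	145.0	6.0
AB1S	SQX	140.0	190.0	260.0	300.0	175.0	47.0	140.0	65.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
BBS1	SQX	140.0	205.0	260.0	300.0	164.0	47.0	140.0	65.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
BB1S	SQX	140.0	190.0	242.0	300.0	175.0	60.0	140.0	65.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
BB2S	SQX	140.0	190.0	260.0	321.0	175.0	47.0	140.0	50.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
NS1S	SQX	140.0	190.0	260.0	300.0	151.0	47.0	140.0	65.0	267.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
NS02	SQX	140.0	171.0	260.0	300.0	175.0	74.0	140.0	65.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
NS03	SQX	140.0	190.0	281.0	300.0	175.0	47.0	140.0	35.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
NS04	SQX	140.0	190.0	260.0	277.0	175.0	47.0	140.0	65.0	283.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
NS05	SQX	140.0	154.0	260.0	300.0	200.0	47.0	140.0	65.0	250.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	155.0	155.0	6.0
ZZ1S	ZZZ	95.0	240.0	295.0	65.0	185.0	175.0	145.0	65.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	45.0	150.0	6.0
ZZ2S	ZZZ	95.0	255.0	295.0	65.0	174.0	175.0	145.0	65.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	45.0	150.0	6.0
ZZS1	ZZZ	95.0	240.0	277.0	65.0	185.0	188.0	145.0	65.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	45.0	150.0	6.0
ZZS2	ZZZ	95.0	240.0	295.0	86.0	185.0	175.0	145.0	50.0	205.0	4.0	4.5	4.5	5.0	3.5	4.0	4.0	5.0	5.0	45.0	150.0	6.0
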