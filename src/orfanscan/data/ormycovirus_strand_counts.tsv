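segment	length	library	plus	minus
ElaOMV1_RNA1	3192	DMGA	0	0
ElaOMV1_RNA1	3192	DMGE	0	0
ElaOMV1_RNA1	3192	DMGD	0	0
ElaOMV1_RNA1	3192	PMA	3360	1450
ElaOMV1_RNA1	3192	PMGA	0	0
ElaOMV1_RNA2	1543	DMGA	0	0
ElaOMV1_RNA2	1543	DMGE	0	0
ElaOMV1_RNA2	1543	DMGD	0	0
ElaOMV1_RNA2	1543	PMA	1814	258
ElaOMV1_RNA2	1543	PMGA	0	0
ElaOMV2_RNA1	2478	DMGA	0	0
ElaOMV2_RNA1	2478	DMGE	0	0
ElaOMV2_RNA1	2478	DMGD	0	0
ElaOMV2_RNA1	2478	PMA	518	3262
ElaOMV2_RNA1	2478	PMGA	0	0
ElaOMV2_RNA2	1875	DMGA	0	0
ElaOMV2_RNA2	1875	DMGE	0	0
ElaOMV2_RNA2	1875	DMGD	0	0
ElaOMV2_RNA2	1875	PMA	462	2436
ElaOMV2_RNA2	1875	PMGA	0	0
PvlaOMV1_RNA1	3040	DMGA	0	0
PvlaOMV1_RNA1	3040	DMGE	1028	464
PvlaOMV1_RNA1	3040	DMGD	410	268
PvlaOMV1_RNA1	3040	PMA	0	0
PvlaOMV1_RNA1	3040	PMGA	3816	1400
PvlaOMV1_RNA2	1555	DMGA	0	0
PvlaOMV1_RNA2	1555	DMGE	752	206
PvlaOMV1_RNA2	1555	DMGD	382	160
PvlaOMV1_RNA2	1555	PMA	0	0
PvlaOMV1_RNA2	1555	PMGA	858	132
PvlaOMV3_RNA1	2406	DMGA	542	2112
PvlaOMV3_RNA1	2406	DMGE	58	186
PvlaOMV3_RNA1	2406	DMGD	768	2570
PvlaOMV3_RNA1	2406	PMA	184	656
PvlaOMV3_RNA1	2406	PMGA	834	2954
PvlaOMV3_RNA2	1771	DMGA	702	2458
PvlaOMV3_RNA2	1771	DMGE	190	410
PvlaOMV3_RNA2	1771	DMGD	888	2114
PvlaOMV3_RNA2	1771	PMA	210	850
PvlaOMV3_RNA2	1771	PMGA	722	2122
PvlaOMV4_RNA1	2554	DMGA	588	6
PvlaOMV4_RNA1	2554	DMGE	0	0
PvlaOMV4_RNA1	2554	DMGD	0	0
PvlaOMV4_RNA1	2554	PMA	0	0
PvlaOMV4_RNA1	2554	PMGA	0	0
PvlaOMV4_RNA2	1757	DMGA	1020	2
PvlaOMV4_RNA2	1757	DMGE	0	0
PvlaOMV4_RNA2	1757	DMGD	0	0
PvlaOMV4_RNA2	1757	PMA	0	0
PvlaOMV4_RNA2	1757	PMGA	0	0
PvlaOMV5_RNA1	2406	DMGA	0	0
PvlaOMV5_RNA1	2406	DMGE	0	0
PvlaOMV5_RNA1	2406	DMGD	402	30
PvlaOMV5_RNA1	2406	PMA	0	0
PvlaOMV5_RNA1	2406	PMGA	0	0
PvlaOMV5_RNA2	1788	DMGA	0	0
PvlaOMV5_RNA2	1788	DMGE	0	0
PvlaOMV5_RNA2	1788	DMGD	276	38
PvlaOMV5_RNA2	1788	PMA	0	0
PvlaOMV5_RNA2	1788	PMGA	0	0
ElaOMV3_RNA1	2058	DMGA	0	0
ElaOMV3_RNA1	2058	DMGE	0	14
ElaOMV3_RNA1	2058	DMGD	0	0
ElaOMV3_RNA1	2058	PMA	0	0
ElaOMV3_RNA1	2058	PMGA	834	3630
ElaOMV3_RNA2	1871	DMGA	0	0
ElaOMV3_RNA2	1871	DMGE	12	52
ElaOMV3_RNA2	1871	DMGD	2	16
ElaOMV3_RNA2	1871	PMA	0	0
ElaOMV3_RNA2	1871	PMGA	588	2352
ElaOMV4_RNA1	2548	DMGA	0	0
ElaOMV4_RNA1	2548	DMGE	0	0
ElaOMV4_RNA1	2548	DMGD	0	0
ElaOMV4_RNA1	2548	PMA	0	0
ElaOMV4_RNA1	2548	PMGA	1568	44
ElaOMV4_RNA2	1881	DMGA	0	0
ElaOMV4_RNA2	1881	DMGE	0	0
ElaOMV4_RNA2	1881	DMGD	0	0
ElaOMV4_RNA2	1881	PMA	0	0
ElaOMV4_RNA2	1881	PMGA	4244	88
SbOMV1_RNA1	2392	Yeast	13262	119150
SbOMV1_RNA2	1726	Yeast	14410	150204
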