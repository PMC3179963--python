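# Geological stages, Carboniferous -> Quaternary; ages in Ma (ICS-derived).
# stage	period	base_ma	top_ma
Tournaisian	Carboniferous	358.9	346.7
Visean	Carboniferous	346.7	330.9
Serpukhovian	Carboniferous	330.9	323.2
Bashkirian	Carboniferous	323.2	315.2
Moscovian	Carboniferous	315.2	307.0
Kasimovian	Carboniferous	307.0	303.7
Gzhelian	Carboniferous	303.7	298.9
Asselian	Permian	298.9	295.0
Sakmarian	Permian	295.0	290.1
Artinskian	Permian	290.1	283.5
Kungurian	Permian	283.5	272.3
Roadian	Permian	272.3	268.8
Wordian	Permian	268.8	265.1
Capitanian	Permian	265.1	259.9
Wuchiapingian	Permian	259.9	254.2
Changhsingian	Permian	254.2	252.2
Induan	Triassic	252.2	251.2
Olenekian	Triassic	251.2	247.2
Anisian	Triassic	247.2	242.0
Ladinian	Triassic	242.0	237.0
Carnian	Triassic	237.0	227.0
Norian	Triassic	227.0	208.5
Rhaetian	Triassic	208.5	201.3
Hettangian	Jurassic	201.3	199.3
Sinemurian	Jurassic	199.3	190.8
Pliensbachian	Jurassic	190.8	182.7
Toarcian	Jurassic	182.7	174.1
Aalenian	Jurassic	174.1	170.3
Bajocian	Jurassic	170.3	168.3
Bathonian	Jurassic	168.3	166.1
Callovian	Jurassic	166.1	163.5
Oxfordian	Jurassic	163.5	157.3
Kimmeridgian	Jurassic	157.3	152.1
Tithonian	Jurassic	152.1	145.0
Berriasian	Cretaceous	145.0	139.8
Valanginian	Cretaceous	139.8	132.9
Hauterivian	Cretaceous	132.9	129.4
Barremian	Cretaceous	129.4	125.0
Aptian	Cretaceous	125.0	113.0
Albian	Cretaceous	113.0	100.5
Cenomanian	Cretaceous	100.5	93.9
Turonian	Cretaceous	93.9	89.8
Coniacian	Cretaceous	89.8	86.3
Santonian	Cretaceous	86.3	83.6
Campanian	Cretaceous	83.6	72.1
Maastrichtian	Cretaceous	72.1	66.0
Danian	Paleogene	66.0	61.6
Selandian	Paleogene	61.6	59.2
Thanetian	Paleogene	59.2	56.0
Ypresian	Paleogene	56.0	47.8
Lutetian	Paleogene	47.8	41.2
Bartonian	Paleogene	41.2	37.8
Priabonian	Paleogene	37.8	33.9
Rupelian	Paleogene	33.9	28.1
Chattian	Paleogene	28.1	23.03
Aquitanian	Neogene	23.03	20.44
Burdigalian	Neogene	20.44	15.97
Langhian	Neogene	15.97	13.82
Serravallian	Neogene	13.82	11.63
Tortonian	Neogene	11.63	7.246
Messinian	Neogene	7.246	5.333
Zanclean	Neogene	5.333	3.6
Piacenzian	Neogene	3.6	2.588
Gelasian	Quaternary	2.588	1.806
Calabrian	Quaternary	1.806	0.781
Middle_Pleistocene	Quaternary	0.781	0.126
Late_Pleistocene	Quaternary	0.126	0.0117
Holocene	Quaternary	0.0117	0.0
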