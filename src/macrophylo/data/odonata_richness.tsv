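# Described extant species per odonate family (World Odonata List counts).
# family	species_count
Aeshnidae	441
Amphipterygidae	12
Austropetaliidae	12
Calopterygidae	176
Chlorocyphidae	151
Chlorogomphidae	45
Chlorolestidae	35
Coenagrionidae	1121
Cordulegastridae	51
Cordulephyidae	5
Corduliidae	244
Dicteriadidae	2
Epallagidae	69
Epiophlebiidae	2
Gomphidae	923
Hemiphlebiidae	1
Hypolestidae	116
Isostictidae	45
Lestidae	152
Lestoideidae	14
Libellulidae	986
Lindeniidae	32
Macromiidae	123
Megapodagrionidae	193
Neopetaliidae	1
Perilestidae	19
Petaluridae	12
Platycnemididae	227
Platystictidae	214
Polythoridae	59
Protoneuridae	259
Pseudolestidae	1
Pseudostigmatidae	19
Synthemistidae	43
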