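name	sequence
sli-miR-211	CUGUGCGUUGUACACACGGCUA
sli-miR-125	UCACUGAGACCAAAACUCCUGA
sli-miR-283a	UAAGUAGUAGCUUUAAUUCU
sli-miR-928c-1	CUGGCUGUGGAAGCUGGCGAA
sli-miR-13	CACAUCACUAGGGCUGUGAUA
sli-miR-10	ACAAAUUCGGAUCAAAAGACA
sli-miR-1890a-1	UGACAUCUUUGAUUAGGUCU
sli-miR-286	UGAUUAGACCUACACACUCGCG
sli-miR-263b-1	AUUGACACCGGAAGAAUUCGC
sli-miR-305-1	AUUGUACUUCUUGUUGGUCUG
sli-miR-283b	UUAAUAACCACGCUAAUAUUUA
sli-miR-283c	AAAAUGUCGCUGGUAAUUCC
sli-miR-79	AUGCUAUUUUAAAUAUAGCUUUA
sli-miR-954	UCUGGGUGUCAUUGUGUAU
sli-miR-981	UUCGUAUGACAUGAAACCUG
sli-miR-31a	CACAAUAUGUCGCGUAGCUGA
sli-miR-989	UGUGAUGCUAAUGUAGAUGCUAC
sli-miR-210	UUGUUCGUGAUCGCAGCGGCUU
sli-miR-1006	UAAGAAUAGGAAGAACUCGAAUUU
sli-miR-6	AAAAAGACCAGCCCUCUGGUA
sli-miR-1890a-2	UGACAUCUUUGAUUAGGUCU
sli-miR-7	UGAGAUAAAGGUUGUUUUGU
sli-miR-33a	GUGCAUUUGUAGUCGCAUU
sli-miR-981	UUCGUUGUAAGAAACUUACA
sli-miR-305-2	AUUGUACUUCUUGUUGGUCUG
sli-miR-279a	UGACUAGCUCCCCCCUCAC
sli-miR-34	UGACAGUGUGGACAGGUGGC
sli-miR-279b	UGACGAGAUGCACUCAU
sli-miR-33b	GUGCAUUUGUAGUUGCAUUGCA
sli-miR-928b	GUGGCUGUAGAGGCGGCGAC
sli-miR-1890b	UGACAUAAUAACGAUUUCA
sli-miR-928a	CUGGCUGUGGAGCUGGCGCU
sli-miR-970	ACAUACUACACUACCCGGCUAU
sli-miR-928c-2	CUGGCUGUGGAAGCUGGCGAA
sli-miR-71	UGAAAGACUGGUGUGAGUGA
sli-miR-1000	ACUCCUGUCCAAGACAAUAA
sli-miR-29b	GCUGAGCCCAAAUGGGGCUA
sli-miR-263b-2	GUGCAUACUUCAUGCCAAG
sli-miR-983	UCAUUAGAUCAUACGCACUAU
sli-miR-307	UCAGCAUCUCCUUGGGUGAC
sli-miR-1175	UUACUUCGUGAGAGUAGAAACUCA
sli-miR-316	UGUGUUUUUCACUUUGCUGCAG
sli-miR-184	UCGACGAACAACUAUAAGGG
sli-miR-15	CGGACGGAGUAGUCUUUAGGG
sli-miR-278	GCCCAUUUGACUUGCCGUCCA
sli-miR-14	CGGGGAGAGAACUGGAAGAGG
sli-miR-2771	UAACAUUAUGAGGAUGGGUUGAACUG
sli-miR-2809	AAAACAGCAGACGGAUCACCUGAU
sli-miR-3001	AACUCUACAAUUAUUUAAAUUUA
sli-miR-3242	CACGCGGGCGGGCGUAUCGCGUUGGA
sli-miR-3279	UAUGUUAUACAAUAUUUAUGACU
sli-miR-3291	AAAUUCAUAUAUUUAGGUACAAA
sli-miR-3290	UGUGUGAUUAUACUUAUGAUUUU
sli-miR-3329	UCUGUAAUAAAUAAUUGUAUGU
sli-miR-1814a	AGGGUUUUUGAUUUUGUUUU
sli-miR-3375	GAAAAUCUUUGAAAAAUUUGGAAUA
sli-miR-2478	UGGUGUCAGAAGUGGGAUCC
sli-miR-2507a	UUUUACGCACAAAAUUGUACAAC
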