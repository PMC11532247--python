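species,authority,wfo_id,citation,rfc,ri,cvi,cii,rank_rfc,rank_ri,rank_cii,rank_cvi
Terminalia arjuna,(Roxb. ex DC.) Wight & Arn.,wfo-0000407013,68,0.468,0.515,0.455,0.82,2,1,8,6
Swertia chirata,Buch.-Ham. ex Wall.,wfo-0000498213,70,0.482,0.507,0.068,0.48,1,2,15,23
Azadirachta indica,A.Juss.,wfo-0000557668,64,0.441,0.504,0.713,0.91,3,3,3,1
Terminalia bellirica,(Gaertn.) Roxb.,wfo-0001296467,63,0.434,0.489,0.474,0.737,4,4,10,5
Ocimum tenuiflorum,L.,wfo-0001296467,63,0.434,0.481,0.45,0.875,5,5,5,7
Aloe vera,(L.) Burm.f.,wfo-0000758976,61,0.42,0.476,0.579,0.931,6,6,1,2
Centella asiatica,(L.) Urb.,wfo-0000594096,59,0.406,0.463,0.539,0.896,7,7,4,3
Cassia tora,L.,wfo-0000165003,6,0.041,0.459,0.007,0.124,50,8,45,44
Abroma augustum,(L.) L.f.,wfo-0000511487,58,0.4,0.44,0.161,0.455,8,9,16,15
Terminalia chebula,Retz.,wfo-0000406875,55,0.379,0.438,0.491,0.875,9,10,6,4
Heliotropium indicum,L.,wfo-0000718658,45,0.31,0.376,0.196,0.427,11,11,20,13
Adhatoda vasica,Nees,wfo-0000520605,46,0.317,0.372,0.183,0.489,10,12,14,14
Phyllanthus emblica,L.,wfo-0000270932,42,0.289,0.359,0.396,0.924,13,13,2,8
Allium sativum,L.,wfo-0000757248,43,0.296,0.353,0.292,0.834,12,14,7,9
Curcuma longa,L.,wfo-0000365771,37,0.255,0.331,0.226,0.615,15,15,12,11
Asparagus racemosus,Willd.,wfo-0000634415,41,0.282,0.317,0.049,0.296,14,16,31,27
Aegle marmelos,(L.) Corrêa,wfo-0000521533,33,0.227,0.311,0.274,0.813,22,17,9,10
Ficus hispida,L.f.,wfo-0000688701,35,0.241,0.307,0.197,0.689,19,18,11,12
Acmella oleracea,(L.) R.K.Jansen,wfo-0000043646,36,0.248,0.298,0.094,0.427,17,19,21,18
Vitex negundo,L.,wfo-0000333303,37,0.255,0.291,0.04,0.268,16,20,33,31
Paederia foetida,L.,wfo-0000262308,34,0.234,0.286,0.109,0.524,21,22,13,16
Typhonium trilobatum,(L.) Schott,wfo-0000328982,34,0.234,0.286,0.078,0.379,20,21,22,20
Ceiba speciosa,"(A.St.-Hil., A.Juss. & Cambess.) Ravenna",wfo-0000592612,9,0.062,0.286,0.01,0.137,47,23,44,41
Nigella sativa,L.,wfo-0000380671,31,0.213,0.285,0.109,0.434,25,24,18,17
Mikania scandens,L. Willd.,wfo-0000009030,35,0.241,0.278,0.046,0.324,18,25,25,29
Calotropis procera,(Aiton) Dryand,wfo-0000581500,29,0.2,0.276,0.086,0.365,26,26,23,19
Moringa oleifera,Lam.,wfo-0001085051,15,0.103,0.273,0.048,0.317,41,27,28,28
Amaranthus spinosus,L.,wfo-0000530495,31,0.213,0.269,0.06,0.317,23,28,29,25
Dracaena trifasciata,(Prain) Mabb.,wfo-0001424422,7,0.048,0.264,0.005,0.117,49,29,46,48
Smilax macrophylla,Willd.,wfo-0000742719,21,0.144,0.245,0.062,0.365,35,30,24,24
Piper nigrum,L.,wfo-0000486494,26,0.179,0.243,0.07,0.441,29,31,17,21
Tribulus terrestris,L.,wfo-0000457857,26,0.179,0.243,0.051,0.324,31,32,26,26
Artocarpus lakoocha,Roxb. ex Buch.-Ham.,wfo-0000550516,20,0.137,0.242,0.07,0.434,36,33,19,22
Sida cordifolia,L.,wfo-0000501705,29,0.2,0.241,0.024,0.206,27,34,37,34
Diospyros malabarica,(Desr.) Kostel.,wfo-0000649282,17,0.117,0.239,0.044,0.324,39,35,27,30
Ferula asafoetida,H.Karst.,wfo-0000686457,31,0.213,0.237,0.013,0.213,24,36,34,38
Achyranthes aspera,L.,wfo-0000516177,26,0.179,0.224,0.022,0.213,28,37,35,35
Cassia angustifolia,M.Vahl,wfo-0000186988,26,0.179,0.224,0.021,0.206,30,38,38,37
Nicotiana plumbaginifolia,Viv.,wfo-0001023911,10,0.068,0.221,0.006,0.11,45,39,47,47
Echinopsis pachanoi,(Britton & Rose) H.Friedrich & G.D.Rowley,wfo-0000662239,11,0.075,0.214,0.012,0.186,44,40,39,39
Crinum asiaticum,L.,wfo-0000764396,24,0.165,0.213,0.029,0.303,32,41,30,32
Plumbago indica,L.,wfo-0001095164,12,0.082,0.21,0.008,0.11,42,42,48,42
Jatropha curcas,L.,wfo-0000219580,17,0.117,0.209,0.022,0.213,38,43,36,36
Erythrina variegata,L.,wfo-0000181193,16,0.11,0.208,0.029,0.296,40,44,32,33
Clerodendrum viscosum,Vent.,wfo-0000887709,23,0.158,0.186,0.007,0.158,33,45,40,43
Sterculia villosa,Roxb.,wfo-0001140523,18,0.124,0.184,0.011,0.158,37,46,41,40
Piper longum,L.,wfo-0000486013,8,0.055,0.182,0.002,0.082,48,47,49,50
Scoparia dulcis,L.,wfo-0000495138,22,0.151,0.179,0.006,0.151,34,48,42,45
Abelmoschus moschatus,Medik.,wfo-0000510888,9,0.062,0.175,0.003,0.082,46,49,50,49
Alocasia indica,Schott,wfo-0000949143,11,0.075,0.169,0.006,0.151,43,50,43,46
Pouzolzia zeylanica,(L.) Benn.,wfo-0000472777,5,0.034,0.135,0,0.034,51,51,51,51
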