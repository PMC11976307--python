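province	prefecture	county	its_codes	coi_codes	combined_codes	shared_codes	sample_size	classification	core_status
Gansu	Gannan	Maqu	F01	H23;H24	F01H23;F01H24		2	Unique	core
Gansu	Gannan	Xiahe	F01	H03	F01H03	F01H03:a	1	Shared	core
Gansu	Zhangye	Minle	F02	H01	F02H01	F02H01:a	6	Shared	non-core
Qinghai	Guoluo	Darlag	F01;F02	H02;H06	F01H02;F02H06	F01H02:b	3	1 Unique+1 Shared	mixed
Qinghai	Guoluo	Gadê	F01	H02	F01H02	F01H02:b	3	Shared	core
Qinghai	Guoluo	Maqên	F01;F07	H01;H02;H03;H06;H52;H67;H68;H69;H70;H71;H72;H73;H74	F01H01;F01H02;F01H03;F01H06;F01H52;F01H67;F01H68;F01H69;F01H70;F01H71;F01H72;F01H73;F01H74;F07H02;F07H03	F01H02:b;F01H03:a	57	13 Unique+2 Shared	mixed
Qinghai	Haibei	Gangca	F02	H01	F02H01	F02H01:ab	3	Shared	non-core
Qinghai	Haibei	Menyuan	F02;F13	H01;H22	F02H01;F13H22	F02H01:ab	4	1 Unique+1 Shared	non-core
Qinghai	Haibei	Qilian	F02	H01	F02H01	F02H01:ab	12	Shared	non-core
Qinghai	Haidong	Huzhu	F02;F05;F10	H01;H53	F02H01;F02H53;F05H01;F10H01	F02H01:ab	7	3 Unique+1 Shared	non-core
Qinghai	Haidong	Ledu	F23	H18	F23H18		1	Unique	non-core
Qinghai	Haidong	Minhe	F01	H54	F01H54		1	Unique	non-core
Qinghai	Hainan	Gonghe	F02	H01	F02H01	F02H01:ab	5	Shared	non-core
Qinghai	Haixi	Tianjun	F02;F05;F17	H01;H25;H26	F02H01;F05H25;F17H26	F02H01:ab	8	2 Unique+1 Shared	non-core
Qinghai	Xining	Datong	F02	H01	F02H01	F02H01:ab	3	Shared	non-core
Qinghai	Xining	Huangzhong	F01	H18	F01H18		1	Unique	non-core
Qinghai	Yushu	Zadoi	F01	H02;H04	F01H02;F01H04	F01H02:b;F01H04:a	3	Shared	core
Sichuan	Aba	Heishui	F05	H19	F05H19		1	Unique	non-core
Sichuan	Aba	Hongyuan	F03	H19	F03H19		1	Unique	non-core
Sichuan	Aba	Xiaojin	F06;F08;F15	H08;H12	F06H08;F08H08;F08H12;F15H08		5	Unique	non-core
Sichuan	Aba	Zamtang	F02	H55	F02H55		1	Unique	non-core
Sichuan	Garzê	Baiyü	F01;F03	H61;H62	F01H62;F03H61		2	Unique	non-core
Sichuan	Garzê	Batang	F01;F02	H63;H64	F01H63;F02H64		2	Unique	non-core
Sichuan	Garzê	Dawu	F06	H20	F06H20		1	Unique	non-core
Sichuan	Garzê	Dêgê	F01	H60	F01H60		1	Unique	non-core
Sichuan	Garzê	Garzê	F01	H58	F01H58		1	Unique	non-core
Sichuan	Garzê	Luhuo	F01	H57	F01H57		1	Unique	non-core
Sichuan	Garzê	Sêrtar	F01	H56	F01H56		1	Unique	non-core
Sichuan	Garzê	Sêrxü	F01	H59	F01H59		1	Unique	core
Sichuan	Garzê	Yajiang	F01	H65	F01H65		1	Unique	non-core
Xizang	Lhasa	Chengguan	F01	H11	F01H11	F01H11:b	2	Shared	non-core
Xizang	Lhasa	Damxung	F01	H33	F01H33		1	Unique	core
Xizang	Lhasa	Doilungdêqên	F01	H37	F01H37		1	Unique	non-core
Xizang	Lhasa	Lhünzhunb	F01	H34	F01H34		1	Unique	non-core
Xizang	Lhasa	Maizhokunggar	F01;F16	H12;H14	F01H14;F16H12		3	Unique	non-core
Xizang	Lhasa	Nyêmo	F01	H05	F01H05	F01H05:b	1	Shared	non-core
Xizang	Nagqu	Baqên	F01	H15;H29	F01H15;F01H29	F01H15	2	1 Unique+1 Shared	mixed
Xizang	Nagqu	Biru	F01	H04;H13;H15;H28	F01H04;F01H13;F01H15;F01H28	F01H04:ab;F01H13;F01H15	5	1 Unique+3 Shared	mixed
Xizang	Nagqu	Lhari	F01	H13;H30	F01H13;F01H30	F01H13	2	1 Unique+1 Shared	non-core
Xizang	Nagqu	Seni	F01	H04;H16;H17	F01H04;F01H16;F01H17	F01H04:ab;F01H17:b	4	1 Unique+2 Shared	core
Xizang	Nagqu	Nyainrong	F01;F07	H04	F01H04;F07H04	F01H04:ab	2	1 Unique+1 Shared	core
Xizang	Nagqu	Sog	F01	H04	F01H04	F01H04:ab	1	Shared	core
Xizang	Nyingch	Bomi	F01	H04;H17;H75	F01H04;F01H17;F01H75	F01H04:ab;F01H17:b	3	1 Unique+2 Shared	core
Xizang	Nyingch	Gongbo′gyamda	F03	H46	F03H46		1	Unique	non-core
Xizang	Nyingch	Mainling	F11;F12;F21	H09;H49;H50	F11H49;F12H09;F21H50	F12H09	3	2 Unique+1 Shared	non-core
Xizang	Nyingch	Langxian	F20;F26	H05;H48	F20H48;F26H05		2	Unique	non-core
Xizang	Nyingch	Bayi	F11;F12;F22;F25	H09;H27	F11H27;F12H09;F22H09;F25H09	F12H09	4	3 Unique+1 Shared	non-core
Xizang	Nyingch	Zayü	F01;F03	H04;H76;H51	F01H04;F01H76;F03H51	F01H04:ab	3	2 Unique+1 Shared	mixed
Xizang	Qamdo	Baxoi	F01	H04	F01H04	F01H04:ab	1	Shared	core
Xizang	Qamdo	Dêngqên	F01	H04;H78	F01H04;F01H78	F01H04:ab	2	1 Unique+1 Shared	core
Xizang	Qamdo	Gonjo	F01	H35	F01H35		1	Unique	non-core
Xizang	Qamdo	Jomda	F01	H40	F01H40		1	Unique	non-core
Xizang	Qamdo	Lhorong	F01	H36	F01H36		1	Unique	core
Xizang	Qamdo	Riwoqê	F01	H04	F01H04	F01H04:ab	2	Shared	core
Xizang	Qamdo	Zhag′yab	F01	H32	F01H32		1	Unique	core
Xizang	Qamdo	Zogang	F01	H38;H39	F01H38;F01H39		2	Unique	non-core
Xizang	Shannan	Comai	F01	H07	F01H07		1	Unique	non-core
Xizang	Shannan	Cona	F04	H07	F04H07		1	Unique	non-core
Xizang	Shannan	Gyaca	F01;F03;F04	H10	F01H10;F03H10;F04H10		3	Unique	non-core
Xizang	Shannan	Lhozhag	F04	H45	F04H45		1	Unique	non-core
Xizang	Shannan	Lhünzê	F03	H07;H77	F03H07;F03H77	F03H07	2	1 Unique+1 Shared	non-core
Xizang	Shannan	Nêdong	F04	H05	F04H05	F04H05:b	1	Shared	non-core
Xizang	Shannan	Qusum	F03	H05;H07	F03H05;F03H07	F03H07	2	1 Unique+1 Shared	non-core
Xizang	Shannan	Zhanang	F01	H05	F01H05	F01H05:b	1	Shared	non-core
Xizang	Xigazê	Dinggyê	F04	H44	F04H44		1	Unique	non-core
Xizang	Xigazê	Gamba	F01	H05	F01H05	F01H05:b	1	Shared	non-core
Xizang	Xigazê	Gyirong	F19	H43	F19H43		1	Unique	non-core
Xizang	Xigazê	Lhazê	F04	H05	F04H05	F04H05:b	1	Shared	non-core
Xizang	Xigazê	Namling	F01	H05	F01H05	F01H05:b	1	Shared	non-core
Xizang	Xigazê	Nyalam	F01	H41	F01H41		1	Unique	non-core
Xizang	Xigazê	Tingri	F01	H42	F01H42		1	Unique	non-core
Xizang	Xigazê	Samzhubzê	F01;F09	H11;H31	F01H11;F09H31	F01H11:b	2	1 Unique+1 Shared	non-core
Xizang	Xigazê	Yadong	F09	H47	F09H47		1	Unique	non-core
Yunnan	Diqing	Dêqên	F24	H66	F24H66		1	Unique	non-core
Yunnan	Lijiang	Yulong	F03	H21	F03H21		1	Unique	non-core
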