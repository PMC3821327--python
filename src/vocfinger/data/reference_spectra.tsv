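sample	retention_time	name	spectrum	identification
BAD	1.688	Acetone	43:999;58:167;42:112	Acetone, dimethyl diazene
Control	1.694	Acetone	43:999;45:514;42:161;58:158;41:126	Acetone, 1-methylethyl hydroperoxide
BAD	1.714	Isopropyl alcohol	45:999;43:270;41:137;39:101	Isopropyl alcohol
Control	1.721	Dimethyl disulphide	45:999;62:624;47:508;44:307;46:252;61:227;43:172;35:165;42:141;59:103	Dimethyl disulphide
BAD	1.863	Cyclopentane	42:999;55:623;41:409;39:399;70:207;40:178;67:169;43:166;68:141	Cyclopentane, 2-pentene
Control	1.868	Dihydro-3-methyl-2,5-furandione	42:999;55:643;41:450;67:253;44:224;39:187;43:151;70:111;56:108;68:102	Dihydro-3-methyl-2,5-furandione, cyclopentane
BAD	2.051	Acetamide	59:999;44:992;42:783;43:658;39:549;41:413;58:345;40:255;57:238;64:146	Acetamide
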