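channel	domain	segment	start	sequence
α1C	1	o	1	PLLHIALLVL FVIIIYAIIG LELFMGK
α1G	1	o	1	MLGNVLLLCF FVFFIFGIVG VQLWAGL
α1C	2	o	1	SIASLLLLLF LFIIIFSLLG MQLFGGK
α1G	2	o	1	NVATFCMLLM LFIFIFSILG MHLFGCK
α1C	3	o	1	TIGNIVIVTT LLQFMFACIG VALFKGK
α1G	3	o	1	PIGNIVVICC AFFIIFGILG VQLFKGK
α1C	4	o	1	ALPYVALLIV MLFFIYAVII GMQVFGK
α1G	4	o	1	QVGNLGLLFM LLFFIFAALG VELFGDL
α1C	1	p	33	FDNFAFAMLT VFQCITMEGW TDVLY
α1G	1	p	33	FDNIGYAWIA IFQVITLEGW VDIMY
α1C	2	p	33	FDNFPQSLLT VFQILTGEDW NSVMY
α1G	2	p	33	FDSLLWAIVT VFQILTQEDW NKVLY
α1C	3	p	33	FDNVLAAMMA LFTVSTFEGW PELLY
α1G	3	p	33	FDNLGQALMS LFVLASKDGW VDIMY
α1C	4	p	33	FQTFPQAVLL LFRCATGEAW QDIML
α1G	4	p	33	FRNFGMAFLT LFRVSTGDNW NGIMK
α1C	1	i	1	ELPWVYFVSL VIFGSFFVLN LVLGVLSGEF
α1G	1	i	1	FYNFIYFILL IIVGSFFMIN LCLVVIATQF
α1C	2	i	1	MLVCIYFIIL FICGNYILLN VFLAIAYDNL
α1G	2	i	1	S WAALYFIAL MTFGNYVLFN LLVAILVEGF
α1C	3	i	1	VEISIFFIIY IIIIAFFMMN IFVGFVIVTF
α1G	3	i	1	PWMLLYFISF LLIVAFFVLN MFVGVVVENF
α1C	4	i	1	SFAVFYFISF YMLCAFLIIN LFVAVIMDNF
α1G	4	i	1	VI SPIYFVSF VLTAQFVLVN VVIAVLMKHL
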