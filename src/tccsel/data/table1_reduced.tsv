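domain	variant	sequence	e_sol	e_coul
1	α1G	ITLEGWVD	-11	-407
1	α1H	ITLEGWVD	-110	-408
1	α1I	ITLEGWVE	-116	-409
1	Reduced TCC	TLEGWV	-87	-323
2	α1G	LTQEDWNK	-217	-631
2	α1H	LTQEDWNV	-262	-631
2	α1I	LTQEDWNV	-487	-633
2	Reduced TCC	TQEDW	-164	-425
3	α1G	ASKDGWVD	-107	-392
3	α1H	SSKDGWVN	-113	-425
3	α1I	ASKDGWVN	-105	-394
3	Reduced TCC	SKDGW	-101	-303
4	α1G	STGDNWNG	-132	-568
4	α1H	STGDNWNG	-164	-574
4	α1I	STGDNWNG	-177	-574
4	Reduced TCC	TGDNW	-86	-393
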