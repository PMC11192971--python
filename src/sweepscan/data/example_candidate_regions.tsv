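chrom	start	end	methods	genes
OAR1	25000001	25500001	iHS,ROH	FAF1;CDKN2C;TRNAY-GUA;TTC39A;C1H1orf185;RNF11
OAR3	93750001	94250001	iHS,ROH	EXOC6B
OAR3	104750001	105500001	iHS,ROH	BCL2L11;ACOXL
OAR4	68250001	69002893	iHS,ROH	HIBADH;TAX1BP1;JAZF1;EVX1;HOXA1;HOXA2;HOXA3;HOXA4;HOXA5;HOXA9;HOXA10;HOXA11;HOXA13
OAR6	24500001	25000001	iHS,CLR	TRNAC-GCA;H2AFZ;LAMTOR3;DDIT4L;DAPP1;DNAJB14
OAR6	29250001	30022764	iHS,ROH	UNC5C;BMPR1B;PDLIM5
OAR7	35000001	35500001	iHS,ROH	CDAN1;CCNDBP1;EPB42;STARD9;TTBK2;UBR1;TMEM62
OAR10	36250001	36831220	iHS,ROH	GJA3;TRNAG-UCC;GJB2;ZMYM2;PSPC1;PARP4;CENPJ;MPHOSPH8;RNF17;ATP12A
OAR13	51250001	51750001	iHS,ROH	AVP;OXT;MRPS26;GNRH2;TMEM239;C13H20orf141;UBOX5;FASTKD5;VPS16;PCED1A;CPXM1;EBF4;PTPRA
OAR13	52750001	53456146	iHS,ROH	TRNAC-GCA;GINS1;PCMTD2;MYT1;OPRL1;TCEA2;UCKL1;DNAJC5;TPD52L2;ZBTB46;PRPF6;NPBWR2;LKAAEAR1;RGS19;SOX18;SAMD10;ZNF512B;ABHD16B;LIME1;ARFRP1;TNFRSF6B;SRMS;PPDPF;EEF1A2;ZGPAT;RTEL1;STMN3;C13H20orf195;PTK6;KCNQ2;GMEB2
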