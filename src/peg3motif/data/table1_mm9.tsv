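chr	start	end	gene	position
chr2	92274630	92275019	Cry2	promoter
chr2	165835510	165836159	Ncoa3	enhancer (1st intron)
chr4	134039455	134040223	Paqr7	5' enhancer
chr7	133630530	133631055	Tufm	promoter
chr7	107375450	107376157	Pgm2l1	promoter
chr10	79817950	79818511	Plk5	Promoter
chr10	84488497	84489095	Ric8b	3' enhancer
chr11	68908354	68908976	Per1	promoter
chr11	97176776	97177720	Mrpl45	promoter
chr12	110071063	110071473	Slc25a29	promoter
chr14	20902311	20902958	Saysd1	promoter
chr15	9070038	9070407	Skp2	promoter
chr15	96528673	96530275	Slc38a2	promoter
chr15	96539404	96539914	Slc38a2	5' enhancer
chr15	96540631	96541033	Slc38a2	5' enhancer
chr16	92158957	92159769	Ak087806	enhancer (1st intron)
chr17	26641241	26641976	Dusp1	promoter
chr18	30689583	30690271	Pik3c3	3' enhancer
chr19	5811752	5812198	Malat1	3' enhancer
chr19	5844399	5846500	Neat1	promoter
chr19	53444058	53444725	Mxi1	enhancer (intron)
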