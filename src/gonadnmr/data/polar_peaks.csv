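peak_no,delta_ppm,multiplicity,metabolite,moiety,confidence
1,0.9587,d,Valine,gamma-CH3/gamma'-CH3 (isopropyl methyls),assigned
2,1.0000,s,Isoleucine (tentative),delta-CH3 (terminal methyl),tentative
3,1.0521,d,Valine,gamma-CH3/gamma'-CH3 (isopropyl methyls),assigned
4,1.0955,unknown,Unassigned,,unassigned
5,1.3061,d,Threonine,gamma-CH3,assigned
6,1.3390,d,Lactate,beta-CH3,assigned
7,1.4315,m,Lysine (tentative),side-chain CH2 envelope (beta/gamma/delta overlap),tentative
8,1.4715,d,Alanine,beta-CH3,assigned
9,1.6708,m,Arginine (tentative),beta/gamma-CH2 (side-chain methylenes),tentative
10,1.7280,m,Lysine,delta-CH2 (side-chain methylene),assigned
11,1.9052,s,Acetate,CH3,assigned
12,2.0630,s,N-acetylglucosamine (putative),NAc-CH3 (acetamide methyl),putative
13,2.0816,m,Glutamate,beta-CH2,assigned
14,2.1488,m,Glutamine,beta-CH2,assigned
15,2.2327,s,Unassigned,,unassigned
16,2.3570,t,Glutamate,gamma-CH2,assigned
17,2.4600,unknown,Glutamine (tentative),gamma-CH2,tentative
18,2.6797,s,Methylamine,CH3-NH3+ (methyl),assigned
19,2.7913,s,Trimethylamine (tentative),N(CH3)3,tentative
20,2.9100,m,Choline (tentative)/methylamine region,N-methyl region (overlap),tentative
21,3.0362,t,Lysine,epsilon-CH2 (adjacent to NH3+),assigned
22,3.1273,t,Histidine,beta-CH2,assigned
23,3.2040,s,Choline/choline derivatives,N+(CH3)3 (trimethylammonium),assigned
24,3.2298,s,Betaine,N+(CH3)3,assigned
25,3.2488,s,Trimethylamine oxide (TMAO),N+(CH3)3 (amine oxide),assigned
26,3.2665,t,Taurine,CH2-NH3+,assigned
27,3.3074,s,"3,7-Dimethyluric acid (putative)",N-CH3 (xanthine/urate scaffold),putative
28,3.3539,s,Methanol,CH3OH,assigned
29,3.3813,unknown,Methanol (shoulder)/unassigned,,tentative
30,3.4100,s,Unassigned,,unassigned
31,3.5042,m,Unassigned,CH2-O (carbohydrate/ribose/glycerol-type),unassigned
32,3.5101,m,Choline-related (probable),CH2-O (choline moiety),tentative
33,3.5648,s,Glycine,alpha-CH2,assigned
34,3.7611,t,Lysine,Halpha (backbone CH),assigned
35,3.7979,unknown,Alanine,Halpha (backbone CH),assigned
36,3.8532,m,Trehalose/carbohydrate (putative),sugar ring CH envelope,putative
37,3.9000,unknown,Betaine (tentative),CH2-COO-,tentative
38,3.9323,s,Creatine,CH2 (adjacent to guanidino system),assigned
39,3.9800,unknown,Unassigned,,unassigned
40,4.3665,s,Trigonelline,N-CH3 (quaternary N-methyl),assigned
41,5.7910,dm,Uridine,H-5 (pyrimidine CH),assigned
42,5.9940,dm,Pyrimidine nucleoside (uridine/cytidine-like),H-5 (pyrimidine CH),tentative
43,6.1000,d,Purine riboside/ribonucleotide (inosine/IMP-like),H-1' (ribose anomeric proton),tentative
44,6.8000,s,"Phenolic aromatic (vanillic/vanillin-like, putative)",aromatic ring CH,putative
45,6.9070,d,Tyrosine,"H-3,5 (AA'BB' ring CH)",assigned
46,7.1260,s,Histidine,imidazole CH (H-delta2),assigned
47,7.1850,d,Tyrosine,"H-2,6 (AA'BB' ring CH)",assigned
48,7.2662,m,Phenylalanine,aromatic ring CH envelope,assigned
49,7.2870,dm,Tryptophan,indole ring CH (H-5),assigned
50,7.3250,m,Phenylalanine (tentative),aromatic ring CH envelope,tentative
51,7.3410,s,Imidazole,ring CH (H-4/H-5),assigned
52,7.4160,m,Phenylalanine,aromatic ring CH envelope,assigned
53,7.5340,dm,Tryptophan,indole ring CH (H-7),assigned
54,7.5500,s,Uracil,H-6 (pyrimidine CH),assigned
55,7.6850,s,Unassigned,aromatic CH (unknown),unassigned
56,7.7260,sm,Xanthine and/or Tryptophan,purine H-8 and/or indole aromatic CH,tentative
57,7.7730,s,Anserine (putative),imidazole CH (histidine-derived),putative
58,7.8510,s,N-acetyl-L-histidine (putative),imidazole CH,putative
59,7.8620,d,Uridine,H-6 (pyrimidine CH),assigned
60,7.8820,s,Unassigned,aromatic CH (unknown),unassigned
61,7.9730,t,Kynurenine-like (HSQC-consistent; downfield-shifted),aromatic ring CH,tentative
62,8.0000,s,Hypoxanthine,H-8 (purine CH),assigned
63,8.0283,d,Kynurenine,,assigned
64,8.0840,m,Trigonelline (reported),pyridinium ring CH,tentative
65,8.2351,s,Purine riboside/ribonucleotide (inosine/IMP-like),purine H-8 (ring CH),tentative
66,8.2710,s,Imidazole,ring CH (H-4/H-5),assigned
67,8.3460,s,Purine riboside/ribonucleotide (inosine/IMP-like),purine H-2 (ring CH),tentative
68,8.5454,t,Kynurenine,pyridinium ring CH (overlapped),assigned
69,8.5936,s,Adenine nucleotide (AMP-like),adenine H-8 (purine CH),tentative
70,8.6998,m,Kynurenine,,assigned
71,8.8380,m,Trigonelline,pyridinium ring CH (downfield member),assigned
72,9.1260,sm,Trigonelline,pyridinium ring CH (most downfield),assigned
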