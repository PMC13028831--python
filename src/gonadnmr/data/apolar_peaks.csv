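peak_no,delta_ppm,multiplicity,metabolite,moiety,confidence,lipid_class
1,0.6803,unknown,Sterol methyl (C18-CH3),sterol angular methyl (18-CH3),assigned,Sterols (cholesterol-like)
2,0.8806,unknown,Terminal -CH3,terminal methyl of fatty acyl chains (major lipid methyl envelope),assigned,FA in TAG/DAG/MAG/PL
3,0.9739,unknown,omega-3 terminal -CH3,omega-3 methyl (EPA/DHA-type chains),assigned,omega-3 PUFA in TAG/PL
4,1.1150,unknown,Aliphatic methyl/methylene,minor aliphatic resonance (sterol methyls/overlapping lipid methylenes),tentative,Sterols/FA (minor)
5,1.2563,unknown,-(CH2)n-,bulk methylene envelope of fatty acyl chains,assigned,FA in TAG/DAG/MAG/PL
6,1.3022,unknown,-(CH2)n-,bulk methylene envelope of fatty acyl chains,assigned,FA in TAG/DAG/MAG/PL
7,1.4978,unknown,Aliphatic -CH2-,mixed aliphatic region,tentative,TAG/PL (overlap)
8,1.6032,unknown,beta-CH2 to C=O,beta-CH2 to carbonyl (acyl groups; general lipid region),assigned,TAG/PL (non-DHA enriched)
9,1.6757,unknown,beta-CH2 to C=O,beta-CH2 to carbonyl (often increases with PUFA-rich acyl distributions),assigned,PUFA-enriched TAG/PL
10,1.8282,unknown,Aliphatic/allylic overlap,minor overlapped aliphatic signal,tentative,TAG/PL/sterols
11,2.0202,unknown,Allylic -CH2-CH=CH-,allylic methylene (unsaturated acyl chains),assigned,UFA in TAG/PL
12,2.0780,unknown,Allylic -CH2-CH=CH-,allylic methylene (unsaturated acyl chains),assigned,UFA in TAG/PL
13,2.3079,unknown,alpha-CH2 to C=O,alpha-CH2 to carbonyl (acyl groups; broad F1-like region),assigned,TAG/PL/FFA
14,2.3869,unknown,alpha-CH2 to C=O (DHA-sensitive window),DHA marker window (alpha-CH2 near carbonyl for DHA acyl groups/DHA region),assigned,DHA-containing TAG/PL and/or DHA (FFA)
15,2.4764,unknown,Unassigned,unassigned weak resonance,unassigned,Trace/unknown
16,2.7722,unknown,Bis-allylic -CH=CH-CH2-CH=CH-,bis-allylic methylene (PUFA),assigned,PUFA (omega-6/omega-3)
17,2.8094,unknown,Bis-allylic -CH=CH-CH2-CH=CH-,bis-allylic methylene (PUFA),assigned,PUFA (omega-6/omega-3)
18,2.8424,unknown,Bis-allylic -CH=CH-CH2-CH=CH-,bis-allylic methylene (PUFA),assigned,PUFA (omega-6/omega-3)
19,3.1409,unknown,Headgroup methylenes,putative ethanolamine-related methylenes (PE-type region),putative,PL (PE/others)
20,3.3273,unknown,N+(CH3)3,choline trimethylammonium (PC/SM total choline region),assigned,PL (PC/SM)
21,3.4892,unknown,Residual solvent proton(s),MeOH trace (residual solvent/contamination),assigned,
22,3.5343,unknown,Sterol H-3 (-CHOH),sterol C3 proton (H-3; cholesterol-like),assigned,Sterols
23,3.7723,unknown,-CH2-O- (backbone),glycerol/PL backbone region (overlap: DG/MG glycerol + PL backbone methylenes),assigned,DG/MG and/or PL
24,3.9490,unknown,-CH2-O-P- (phosphodiester-linked methylene),phospholipid backbone region (CH2O-P/adjacent backbone methylenes),assigned,PL
25,4.1673,unknown,-CH2-O- (glycerol),glycerol backbone methylenes (MG/DG) with possible PL overlap,assigned,DG/MG and/or PL
26,4.2848,unknown,-CH2-O- (glycerol),"DG/PL backbone methylenes (often used for partial glycerides; overlaps PL)",assigned,"DG (1,2-DG) and/or PL"
27,4.3841,unknown,-CH2-CH2-N+(CH3)3 (choline methylenes),choline methylene region (PC/SM headgroup side-chain),assigned,PL (PC/SM)
28,5.2784,unknown,sn-2 glycerol -CH-O-,TAG glycerol sn-2 CH,assigned,TAG (overlap possible)
29,5.3654,unknown,Olefinic -CH=CH-,olefinic protons of unsaturated acyl chains; can overlap sterol H-6,assigned,UFA in TAG/PL + sterols
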