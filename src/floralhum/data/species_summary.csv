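rank,name,is_control,floral_structure,floral_type,grown_outside,mean_span_mm,span_source,stomata_pct,stomata_n,best_x_model,comparable_x_models,best_z_model,x_max_mm,x_max_replicate,delta_rh_max_pct
1,Fuchsia sp.,0,funnel,flower,1,33.7,7,,,m0,m0,z2,0,(Z),0.05
,T control,1,,,,,,,,m7,m7,z1,-5.01,3,0.06
,TWLP control,1,,,,,,,,m5,m5;m6,z2,-30,3,0.09
2,Nicotiana tabacum,0,funnel,flower,0,23.6,5,,,m2,m2,z2,0,(Z),0.10
,TL control,1,,,,,,,,m5,m5,z2,-30,3,0.10
,TLP control,1,,,,,,,,m4,m4,z2,0,1,0.14
3,Vinca herbacea,0,bell,flower,1,48.6,12,0,5,m7,m7,z0,-2.49,2,0.24
4,Allium ursinum,0,unfused,flower,1,20,a,,,m2,m2,z2,0,(Z),0.24
5,Nepenthes sp.,0,unfused,flower,0,80,b,,,m2,m2,z2,0,(Z),0.26
6,Papaver rhoeas,0,unfused,flower,1,56.4,9,100,5,m3,m3,z2,-4.35,(Z),0.29
7,Euphorbia milii,0,compound inflorescence,inflorescence,0,12,c,,,m6,m6,z2,0,3,0.29
8,Cyanus montanus,0,compound inflorescence,inflorescence,1,53.4,11,,,m7,m7,z2,-1.88,2,0.31
9,Abutilon x milleri,0,funnel,flower,1,30.8,6,0,4,m6,m6,z2,0,1,0.32
10,Campanula sp.,0,bell,flower,0,20.7,3,,,m2,m2,z2,0,(Z),0.36
11,Linum grandiflorum,0,unfused,flower,1,38,3,0,2,m10,m10,z3,7.22,2,0.36
12,Geranium robertianum,0,unfused,flower,1,15.4,11,,,m2,m2,z2,0,(Z),0.41
,TWL control,1,,,,,,,,m2,m2,z0,0,,0.46
13,Tulbaghia violacea,0,funnel,flower,1,29,9,,,m9,m9,z2,0,1,0.52
14,Papaver cambricum,0,unfused,flower,1,48.3,8,100,5,m2,m2,z1,0,,0.58
15,Bellis perennis,0,compound inflorescence,inflorescence,1,18.1,14,0,3,m2,m2,z3,0,(Z),0.58
16,Epilobium hirsutum,0,funnel,flower,1,15.1,7,,,m2,m2,z2,0,(Z),0.59
17,Trifolium pratense,0,umbel inflorescence,inflorescence,1,20.1,9,,,m9,m9,z2,0,4,0.61
18,Lilium sp.,0,funnel,flower,0,93,5,,,m8,m8,z2,-30,4,0.65
19,Clematis chinensis,0,unfused,flower,1,50,d,,,m7,m7,z2,-2.91,1,0.66
20,Cistus greyswood pink,0,unfused,flower,1,43.6,11,,,m2,m2,z3,0,(Z),0.66
21,Cosmos bipinnatus,0,compound inflorescence,inflorescence,0,92.5,6,,,m7,m7,z1,2.99,2,0.67
22,Geranium Roxanne,0,unfused,flower,1,42.6,8,0,4,m7,m7,z3,-1.66,3,0.67
23,Potentilla sp.,0,unfused,flower,1,29,12,,,m7,m7,z1,1.28,1,0.70
24,Coreopsis sp.,0,compound inflorescence,inflorescence,0,46.8,4,0,2,m3,m3,z3,0.94,(Z),0.71
25,Lavandula angustifolia,0,racemose inflorescence,inflorescence,1,18.6,10,,,m6,m6,z2,0,4,0.72
26,Geranium sanguineum,0,unfused,flower,1,41,12,,,m9,m9,z3,0,2,0.79
27,Linum usitatissimum,0,unfused,flower,1,16.7,6,,,m9,m9,z2,0,2,0.80
28,Convolvulus sabatius,0,funnel,flower,1,32.8,12,0,4,m9,m9,z3,0,1,0.87
29,Cyanus segetum,0,compound inflorescence,inflorescence,1,36.4,14,,,m6,m6,z0,0,1,1.10
,TW control,1,,,,,,,,m2,m2,z1,0,,1.17
30,Osteospermum sp.,0,compound inflorescence,inflorescence,0,51.9,10,20,5,m10,m10,z4,5.49,3,1.20
31,Rudbeckia hirta,0,compound inflorescence,inflorescence,1,56.3,10,,,m7,m7,z1,2.97,2,1.25
32,Scabiosa sp.,0,compound inflorescence,inflorescence,0,39.6,5,,,m3,m3,z1,1.61,,1.36
33,Lantana sp.,0,umbel inflorescence,inflorescence,0,42.3,11,,,m2,m2,z1,0,,1.47
34,Achillea millefolium,0,umbel inflorescence,inflorescence,1,33.3,9,,,m3,m3,z1,1.69,,1.73
35,Leucanthemum vulgare,0,compound inflorescence,inflorescence,1,47.2,6,,,m7,m7,z4,2.17,1,1.79
36,Oenothera caespitosa,0,funnel,flower,0,54.2,5,,,m10,m10,z1,2.54,1,1.79
37,Ranunculus lingua,0,unfused,flower,1,35.7,7,,,m7,m7,z3,2.61,2,3.16
38,Eschscholzia californica,0,unfused,flower,1,48.8,9,80,5,m7,m7,z4,21.49,4,3.24
39,Taraxacum agg.,0,compound inflorescence,inflorescence,1,39.3,9,0,4,m9,m9,z4,0,4,3.35
40,Ranunculus acris,0,unfused,flower,1,24,19,0,3,m9,m9,z3,0,2,3.41
41,Xerochrysum bracteatum,0,compound inflorescence,inflorescence,0,48.4,9,0,3,m3,m3,z1,1.41,,3.67
42,Calystegia silvatica,0,funnel,flower,1,61.8,12,,,m8,m8,z1,30,3,3.71
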