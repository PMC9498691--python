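pair_id,name,left_label,right_label
1,Hippocampus,2,1
2,Amygdala,4,3
3,"Anterior temporal lobe, medial part",6,5
4,"Anterior temporal lobe, lateral part",8,7
5,Gyri parahippocampalis et ambiens,10,9
6,"Superior temporal gyrus, posterior part",12,11
7,Middle and inferior temporal gyrus,14,13
8,Lateral occipitotemporal gyrus (fusiform),16,15
9,Cerebellum,18,17
10,Insula,20,21
11,Lateral remainder of occipital lobe,22,23
12,"Cingulate gyrus, anterior part",24,25
13,"Cingulate gyrus, posterior part",26,27
14,Middle frontal gyrus,28,29
15,Posterior temporal lobe,30,31
16,Inferiolateral remainder of parietal lobe,32,33
17,Caudate nucleus,34,35
18,Nucleus accumbens,36,37
19,Putamen,38,39
20,Thalamus,40,41
21,Pallidum,42,43
22,"Lateral ventricle, excluding temporal horn",46,45
23,"Lateral ventricle, temporal horn",48,47
24,Precentral gyrus,50,51
25,Straight gyrus,52,53
26,Anterior orbital gyrus,54,55
27,Inferior frontal gyrus,56,57
28,Superior frontal gyrus,58,59
29,Postcentral gyrus,60,61
30,Superior parietal gyrus,62,63
31,Lingual gyrus,64,65
32,Cuneus,66,67
33,Medial orbital gyrus,68,69
34,Lateral orbital gyrus,70,71
35,Posterior orbital gyrus,72,73
36,Substantia nigra,74,75
37,Subgenual frontal cortex,76,77
38,Subcallosal area,78,79
39,Pre-subgenual frontal cortex,80,81
40,"Superior temporal gyrus, anterior part",82,83
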