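# Urinary-bladder PET measurements in 23 patients (11 M, 12 F) undergoing
# whole-body FDG PET/CT: bladder activity as % of injected activity (NOT
# decay-corrected), time of the (encouraged) first voiding in minutes p.i.,
# and minutes between that voiding and the start of the whole-body scan
# (the bladder bed is imaged ~1.5 min after scan start; scans ~60 min p.i.).
patient,sex,pct_ia,first_void_min,void_to_scan_min
1,M,0.6,43,19
2,M,1.4,46,10
3,F,1.1,42,18
4,F,2.0,41,22
5,M,2.0,42,25
6,F,1.5,40,18
7,F,2.5,40,22
8,M,1.2,46,13
9,M,2.3,48,14
10,M,1.9,42,14
11,M,0.8,48,8
12,F,0.9,49,11
13,F,0.9,44,19
14,M,1.2,44,14
15,F,1.1,43,18
16,M,3.6,41,21
17,F,3.1,43,15
18,F,1.5,46,9
19,F,1.3,44,17
20,F,1.0,44,14
21,F,1.1,41,17
22,M,0.6,44,12
23,M,0.5,48,11
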