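# Reference TIACs (MBq-h/MBq) of the legacy descriptive FDG model of ICRP
# Publication 128, for use as the denominator of the percent-difference
# report. Brain/lungs/liver/heart-wall/UB values are backed out of the
# published percent differences of the revised model; regions absent from
# the legacy model carry no entry and report N/A.
source_region,tiac_mbqh_per_mbq
Brain,2.09E-01
Lung tissue,8.25E-02
Liver,1.29E-01
Heart wall,1.10E-01
UB contents,2.59E-01
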