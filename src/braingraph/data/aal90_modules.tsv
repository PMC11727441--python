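roi	module
PreCG.L	frontal
PreCG.R	frontal
SFGdor.L	prefrontal
SFGdor.R	prefrontal
ORBsup.L	prefrontal
ORBsup.R	prefrontal
MFG.L	prefrontal
MFG.R	prefrontal
ORBmid.L	prefrontal
ORBmid.R	prefrontal
IFGoperc.L	prefrontal
IFGoperc.R	prefrontal
IFGtriang.L	prefrontal
IFGtriang.R	prefrontal
ORBinf.L	prefrontal
ORBinf.R	prefrontal
ROL.L	frontal
ROL.R	frontal
SMA.L	frontal
SMA.R	frontal
OLF.L	prefrontal
OLF.R	prefrontal
SFGmed.L	prefrontal
SFGmed.R	prefrontal
ORBsupmed.L	prefrontal
ORBsupmed.R	prefrontal
REC.L	prefrontal
REC.R	prefrontal
INS.L	frontal
INS.R	frontal
ACG.L	prefrontal
ACG.R	prefrontal
DCG.L	frontal
DCG.R	frontal
PCG.L	parietal
PCG.R	parietal
HIP.L	temporal
HIP.R	temporal
PHG.L	temporal
PHG.R	temporal
AMYG.L	temporal
AMYG.R	temporal
CAL.L	occipital
CAL.R	occipital
CUN.L	occipital
CUN.R	occipital
LING.L	occipital
LING.R	occipital
SOG.L	occipital
SOG.R	occipital
MOG.L	occipital
MOG.R	occipital
IOG.L	occipital
IOG.R	occipital
FFG.L	occipital
FFG.R	occipital
PoCG.L	parietal
PoCG.R	parietal
SPG.L	parietal
SPG.R	parietal
IPL.L	parietal
IPL.R	parietal
SMG.L	parietal
SMG.R	parietal
ANG.L	parietal
ANG.R	parietal
PCUN.L	parietal
PCUN.R	parietal
PCL.L	frontal
PCL.R	frontal
CAU.L	subcortical
CAU.R	subcortical
PUT.L	subcortical
PUT.R	subcortical
PAL.L	subcortical
PAL.R	subcortical
THA.L	subcortical
THA.R	subcortical
HES.L	temporal
HES.R	temporal
STG.L	temporal
STG.R	temporal
TPOsup.L	temporal
TPOsup.R	temporal
MTG.L	temporal
MTG.R	temporal
TPOmid.L	temporal
TPOmid.R	temporal
ITG.L	temporal
ITG.R	temporal
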