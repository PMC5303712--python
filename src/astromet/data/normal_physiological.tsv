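# Normal physiological exchange constraints for the astrocyte network.
# Columns: metabolite (species id), rate in umol/g tissue/min (a-b means a
# range; the upper value is used as the capacity), direction uptake|release.
metabolite	rate	direction
glc	0.16	uptake
lnlc	0.0011	uptake
lnlnca	0.0009	uptake
his	0.0025	uptake
ile	0.0004	uptake
leu	0.0145	uptake
lys	0.011	uptake
met	0.0017	uptake
thr	0.0008	uptake
val	0.0018	uptake
o2	0.515-0.530	uptake
co2	0.530	release
asn	0.0037	uptake
tyr	0.0017	uptake
arg	0.0020	uptake
gly	0.0086	uptake
pro	0.0066	uptake
ser	0.0016	uptake
glu	0.232	uptake
orn	0.0031	uptake
acac	0.0015	uptake
pyr	0.007	uptake
cysi	0.0045	uptake
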