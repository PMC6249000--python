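abbrev	name	hemisphere	in_network
A1	Primary auditory cortex	left	1
A2	Secondary auditory cortex	left	1
Amyg	Amygdala	left	0
CCa	Anterior cingulate cortex	left	1
CCp	Posterior cingulate cortex	left	1
CCr	Retrosplenial cortex	left	1
CCs	Subgenual cingulate cortex	left	1
FEF	Frontal eye field	left	1
G	Gustatory area	left	1
HC	Hippocampus	left	0
Ia	Anterior insula	left	1
Ip	Posterior insula	left	1
M1	Primary motor cortex	left	1
PCi	Inferior parietal cortex	left	1
PCip	Cortex of the intraparietal sulcus	left	1
PCm	Medial parietal cortex	left	1
PCs	Superior parietal cortex	left	1
PFCcl	Centrolateral prefrontal cortex	left	1
PFCdl	Dorsolateral prefrontal cortex	left	1
PFCdm	Dorsomedial prefrontal cortex	left	1
PFCm	Medial prefrontal cortex	left	1
PFCoi	Intermediate orbital prefrontal cortex	left	1
PFCol	Orbitolateral prefrontal cortex	left	1
PFCom	Orbitomedial prefrontal cortex	left	1
PFCpol	Polar prefrontal cortex	left	1
PFCvl	Ventrolateral prefrontal cortex	left	1
PHC	Parahippocampal cortex	left	1
PMCdl	Dorsolateral premotor cortex	left	1
PMCm	Medial (supplementary) premotor cortex	left	1
PMCvl	Ventrolateral premotor cortex	left	1
S1	Primary somatosensory cortex	left	1
S2	Secondary somatosensory cortex	left	1
TCc	Central temporal cortex	left	1
TCi	Inferior temporal cortex	left	1
TCpol	Polar temporal cortex	left	1
TCs	Superior temporal cortex	left	1
TCv	Ventral temporal cortex	left	1
V1	Primary visual cortex	left	1
V2	Secondary visual cortex	left	1
VACd	Dorsal anterior visual cortex	left	1
VACv	Ventral anterior visual cortex	left	1
A1	Primary auditory cortex	right	1
A2	Secondary auditory cortex	right	1
Amyg	Amygdala	right	0
CCa	Anterior cingulate cortex	right	1
CCp	Posterior cingulate cortex	right	1
CCr	Retrosplenial cortex	right	1
CCs	Subgenual cingulate cortex	right	1
FEF	Frontal eye field	right	1
G	Gustatory area	right	1
HC	Hippocampus	right	0
Ia	Anterior insula	right	1
Ip	Posterior insula	right	1
M1	Primary motor cortex	right	1
PCi	Inferior parietal cortex	right	1
PCip	Cortex of the intraparietal sulcus	right	1
PCm	Medial parietal cortex	right	1
PCs	Superior parietal cortex	right	1
PFCcl	Centrolateral prefrontal cortex	right	1
PFCdl	Dorsolateral prefrontal cortex	right	1
PFCdm	Dorsomedial prefrontal cortex	right	1
PFCm	Medial prefrontal cortex	right	1
PFCoi	Intermediate orbital prefrontal cortex	right	1
PFCol	Orbitolateral prefrontal cortex	right	1
PFCom	Orbitomedial prefrontal cortex	right	1
PFCpol	Polar prefrontal cortex	right	1
PFCvl	Ventrolateral prefrontal cortex	right	1
PHC	Parahippocampal cortex	right	1
PMCdl	Dorsolateral premotor cortex	right	1
PMCm	Medial (supplementary) premotor cortex	right	1
PMCvl	Ventrolateral premotor cortex	right	1
S1	Primary somatosensory cortex	right	1
S2	Secondary somatosensory cortex	right	1
TCc	Central temporal cortex	right	1
TCi	Inferior temporal cortex	right	1
TCpol	Polar temporal cortex	right	1
TCs	Superior temporal cortex	right	1
TCv	Ventral temporal cortex	right	1
V1	Primary visual cortex	right	1
V2	Secondary visual cortex	right	1
VACd	Dorsal anterior visual cortex	right	1
VACv	Ventral anterior visual cortex	right	1
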