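# Braak-stage approximation over 36 bilateral Desikan-Killiany ROIs
# (34 cortical parcels + hippocampus + amygdala, left/right averaged).
# Externally sourced configuration following the published tau-PET Braak
# staging approximation; editable -- the package treats this file as data,
# not as code.
I:
  - entorhinal
II:
  - hippocampus
III:
  - parahippocampal
  - fusiform
  - lingual
  - amygdala
IV:
  - middletemporal
  - caudalanteriorcingulate
  - rostralanteriorcingulate
  - posteriorcingulate
  - isthmuscingulate
  - insula
  - inferiortemporal
  - temporalpole
V:
  - superiorfrontal
  - lateralorbitofrontal
  - medialorbitofrontal
  - frontalpole
  - caudalmiddlefrontal
  - rostralmiddlefrontal
  - parsopercularis
  - parsorbitalis
  - parstriangularis
  - lateraloccipital
  - supramarginal
  - inferiorparietal
  - superiortemporal
  - superiorparietal
  - precuneus
  - bankssts
  - transversetemporal
VI:
  - pericalcarine
  - postcentral
  - cuneus
  - precentral
  - paracentral
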