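# Synthetic example of a Braak-stage ROI config.
#
# This file is a SYNTHETIC stand-in illustrating the expected format: stage
# keys map to lists of atlas region *names*, resolved against a user-supplied
# name->id region table at load time.  The names below follow the anatomical
# groupings of the Braak staging scheme (I-II hippocampal formation, III-IV
# limbic/temporal, V-VI widespread neocortex) but are NOT an authoritative
# atlas membership list; edit this file to match your atlas before real use.
braak_1_2:
  - hippocampus
  - parahippocampus
braak_3_4:
  - fusiform
  - amygdala
  - cingulate_anterior
  - cingulate_middle
  - cingulate_posterior
  - temporal_inferior
  - temporal_middle
braak_5_6:
  - frontal_superior
  - frontal_middle
  - frontal_inferior
  - orbitofrontal
  - precentral
  - postcentral
  - paracentral
  - precuneus
  - parietal_superior
  - parietal_inferior
  - supramarginal
  - temporal_superior
  - occipital_medial
  - occipital_lateral
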