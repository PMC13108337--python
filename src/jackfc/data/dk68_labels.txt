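lh_bankssts
lh_caudalanteriorcingulate
lh_caudalmiddlefrontal
lh_cuneus
lh_entorhinal
lh_fusiform
lh_inferiorparietal
lh_inferiortemporal
lh_isthmuscingulate
lh_lateraloccipital
lh_lateralorbitofrontal
lh_lingual
lh_medialorbitofrontal
lh_middletemporal
lh_parahippocampal
lh_paracentral
lh_parsopercularis
lh_parsorbitalis
lh_parstriangularis
lh_pericalcarine
lh_postcentral
lh_posteriorcingulate
lh_precentral
lh_precuneus
lh_rostralanteriorcingulate
lh_rostralmiddlefrontal
lh_superiorfrontal
lh_superiorparietal
lh_superiortemporal
lh_supramarginal
lh_frontalpole
lh_temporalpole
lh_transversetemporal
lh_insula
rh_bankssts
rh_caudalanteriorcingulate
rh_caudalmiddlefrontal
rh_cuneus
rh_entorhinal
rh_fusiform
rh_inferiorparietal
rh_inferiortemporal
rh_isthmuscingulate
rh_lateraloccipital
rh_lateralorbitofrontal
rh_lingual
rh_medialorbitofrontal
rh_middletemporal
rh_parahippocampal
rh_paracentral
rh_parsopercularis
rh_parsorbitalis
rh_parstriangularis
rh_pericalcarine
rh_postcentral
rh_posteriorcingulate
rh_precentral
rh_precuneus
rh_rostralanteriorcingulate
rh_rostralmiddlefrontal
rh_superiorfrontal
rh_superiorparietal
rh_superiortemporal
rh_supramarginal
rh_frontalpole
rh_temporalpole
rh_transversetemporal
rh_insula
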