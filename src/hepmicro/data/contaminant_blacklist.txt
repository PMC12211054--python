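# Default reagent/laboratory contaminant genus blacklist.
# Common kit and environmental contaminant genera reported in low-biomass
# sequencing studies. Replace with a study-specific list via --blacklist.
Afipia
Aquabacterium
Asticcacaulis
Aurantimonas
Beijerinckia
Bosea
Bradyrhizobium
Brevundimonas
Burkholderia
Caulobacter
Chryseobacterium
Craurococcus
Cupriavidus
Curvibacter
Deinococcus
Delftia
Devosia
Duganella
Dyella
Erythrobacter
Filimonas
Herbaspirillum
Hoeflea
Hydrogenophaga
Janthinobacterium
Kingella
Leifsonia
Massilia
Mesorhizobium
Methylobacterium
Methylophilus
Microbacterium
Novosphingobium
Ochrobactrum
Paracoccus
Pedobacter
Pelomonas
Phyllobacterium
Polaromonas
Pseudoxanthomonas
Psychrobacter
Rhizobium
Rhodococcus
Roseateles
Roseomonas
Sediminibacterium
Sphingobium
Sphingopyxis
Tepidimonas
Undibacterium
Variovorax
Xanthobacter
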