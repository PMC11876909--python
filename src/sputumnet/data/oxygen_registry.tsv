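# Curated oxygen-requirement classes for sputum-relevant bacterial genera.
# Classes: aerobe, facultative_anaerobe, obligate_anaerobe, microaerophile, unknown.
# This registry is a package default assembled from standard clinical
# microbiology references; every entry can be overridden by the user
# (see sputumnet.keystone.OxygenRegistry).
genus	oxygen_class
Actinomyces	facultative_anaerobe
Achromobacter	aerobe
Acinetobacter	aerobe
Aggregatibacter	facultative_anaerobe
Atopobium	obligate_anaerobe
Bifidobacterium	obligate_anaerobe
Butyrivibrio	obligate_anaerobe
Campylobacter	microaerophile
Capnocytophaga	facultative_anaerobe
Cardiobacterium	facultative_anaerobe
Clostridium	obligate_anaerobe
Corynebacterium	aerobe
Dialister	obligate_anaerobe
Fusobacterium	obligate_anaerobe
Gemella	facultative_anaerobe
Granulicatella	facultative_anaerobe
Haemophilus	facultative_anaerobe
Kingella	aerobe
Lachnoanaerobaculum	obligate_anaerobe
Lactobacillus	facultative_anaerobe
Leptotrichia	obligate_anaerobe
Megasphaera	obligate_anaerobe
Mogibacterium	obligate_anaerobe
Moraxella	aerobe
Moryella	obligate_anaerobe
Mycoplasma	facultative_anaerobe
Neisseria	aerobe
Oribacterium	obligate_anaerobe
Oscillospira	obligate_anaerobe
Paludibacter	obligate_anaerobe
Parvimonas	obligate_anaerobe
Peptococcus	obligate_anaerobe
Peptostreptococcus	obligate_anaerobe
Porphyromonas	obligate_anaerobe
Prevotella	obligate_anaerobe
Pseudomonas	aerobe
Rothia	facultative_anaerobe
Schwartzia	obligate_anaerobe
Selenomonas	obligate_anaerobe
Stenotrophomonas	aerobe
Streptococcus	facultative_anaerobe
Tannerella	obligate_anaerobe
Treponema	obligate_anaerobe
Turicibacter	obligate_anaerobe
Veillonella	obligate_anaerobe
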