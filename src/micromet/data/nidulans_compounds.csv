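name,formula,source
Cordycepin,C10H13N5O3,curated-literature
Arugosin G,C30H36O6,curated-literature
Asperfuranone,C19H24O5,curated-literature
Aspoquinolone A/B,C27H31NO6,curated-literature
Austinol intermediate (C25H30O7),C25H30O7,curated-literature
Dehydroaustinol,C25H28O8,curated-literature
Dehydrocitreoisocoumarin or 2-acetoacetyl T4HN,C14H12O6,curated-literature
Desacetylaustin or austinol,C25H30O8,curated-literature
Diorcinol,C14H14O3,curated-literature
Emericellamide A,C31H55N5O7,curated-literature
Emericellamide C/D,C30H53N5O7,curated-literature
Emericellamide E/F,C32H57N5O7,curated-literature
Emericellin,C25H28O5,curated-literature
Emodic acid,C15H8O7,curated-literature
A heptaketide (C15H24O2),C15H24O2,curated-literature
Isoaustinone,C25H30O6,curated-literature
Nidulalin A or B,C16H14O6,curated-literature
Nidulol,C10H10O4,curated-literature
Variecoxanthone A,C20H20O5,curated-literature
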