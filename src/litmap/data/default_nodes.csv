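category,parent,child
Ecology,Abiotic Conditions,
Ecology,Abiotic Conditions,Climate
Ecology,Abiotic Conditions,Abiotic Disturbance
Ecology,Abiotic Conditions,Resources
Ecology,Anthropogenic Influences,
Ecology,Anthropogenic Influences,Biological Invasions
Ecology,Anthropogenic Influences,Climate Change
Ecology,Anthropogenic Influences,Land Use
Ecology,Anthropogenic Influences,Pollution
Ecology,Biotic Factors,
Ecology,Biotic Factors,Biotic Disturbance
Ecology,Biotic Factors,Competition
Ecology,Biotic Factors,Facilitation/Mutualism
Ecology,Biotic Factors,Herbivory
Ecology,Biotic Factors,Parasitism & Disease
Ecology,Population Dynamics,
Ecology,Population Dynamics,Demographic Factors
Ecology,Population Dynamics,Population Distribution
Ecology,Population Dynamics,Population Size
Evolution,Genetic Diversity & Systems,
Evolution,Genetic Diversity & Systems,Heritability
Evolution,Genetic Diversity & Systems,Ploidy
Evolution,Genetic Diversity & Systems,Within Individual Variation
Evolution,Genetic Diversity & Systems,Within Population Variation
Evolution,Macroevolution,
Evolution,Macroevolution,Convergent Evolution
Evolution,Macroevolution,Divergent Evolution
Evolution,Macroevolution,Homologous Evolution
Evolution,Macroevolution,Hybridization
Evolution,Macroevolution,Speciation
Evolution,Microevolution,
Evolution,Microevolution,Gene Flow
Evolution,Microevolution,Genetic Drift
Evolution,Microevolution,Mutation
Evolution,Microevolution,Natural Selection
General Characteristics,Cellular & Molecular Biology,
General Characteristics,Growth & Development,
General Characteristics,Physiology,
General Characteristics,Niche,
General Characteristics,Morphology,
General Characteristics,Plasticity,
General Characteristics,Reproduction,
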