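# PLS path model for the demo fixture: treatment -> soil -> community -> plant
blocks:
  treatment: [treatment_score]
  soil: [pH, SMC, NH4, NO3, IN, DOC, DON, TC, TN]
  community: [comm_axis1, comm_axis2]
  plant: [biomass, yield]
paths:
  - [treatment, soil]
  - [treatment, community]
  - [soil, community]
  - [soil, plant]
  - [community, plant]
scheme: path
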