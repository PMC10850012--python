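# Diet composition, prey rows x predator columns, published diet table.
prey\predator,C. idellus,H. molitrix,A. nobilis,C. auratus,Protozoa,Rotifera,Cladocera,Copepoda,Mollusca,Oligochaeta,Chironomidae,Bacteria (water),Bacteria (sediment),Phytoplankton,Feed,Precipitation,Detritus (water),Detritus (sediment)
C. idellus,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H. molitrix,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
A. nobilis,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C. auratus,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Protozoa,0,0.006,0.005,0.001,0,0.003,0.019,0.023,0,0,0,0,0,0,0,0,0,0
Rotifera,0.007,0.011,0.013,0.031,0,0,0.041,0.097,0,0,0,0,0,0,0,0,0,0
Cladocera,0.008,0.013,0.015,0.037,0,0,0,0.129,0,0,0,0,0,0,0,0,0,0
Copepoda,0.027,0.034,0.035,0.011,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Mollusca,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Oligochaeta,0,0,0,0.013,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Chironomidae,0,0,0,0.011,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Bacteria (water),0.015,0.037,0.041,0.051,0.313,0.231,0.131,0.12,0.107,0.113,0.103,0,0,0,0,0,0,0
Bacteria (sediment),0,0,0,0.059,0.135,0.071,0.0803,0.037,0.315,0.321,0.311,0,0,0,0,0,0,0
Phytoplankton,0.087,0.611,0.607,0.413,0.33,0.513,0.591,0.481,0.412,0.453,0.423,0,0,0,0,0,0,0
Feed,0.755,0.115,0.109,0.071,0.001,0.0015,0.0017,0.002,0.001,0.001,0.001,0.05,0.05,0,0,0,0,0
Precipitation,0,0,0,0,0.001,0.001,0.001,0.001,0.001,0.001,0.001,0,0,0,0,0,0,0
Detritus (water),0.101,0.173,0.175,0.131,0.213,0.171,0.128,0.105,0.057,0.034,0.041,0.95,0,0,0,0,0,0
Detritus (sediment),0,0,0,0.171,0.007,0.0085,0.007,0.005,0.107,0.077,0.12,0,0.95,0,0,0,0,0
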