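# 80:20 polyculture grass-carp pond, 18 functional groups; all rates per 300-day season.
# Biomass, P/B, Q/B, EE, imports: published basic-parameter table values.
# Resolved or derived cells:
#   gs: grass carp 0.41, zooplankton 0.65, Mollusca 0.7, bacteria 0.4 per the
#     stated assimilation conventions; other fish 0.2 (carnivore default);
#     Oligochaeta/Chironomidae 0.2, derived from the flow-to-detritus identity.
#   catch = P*EE for fish (fully harvested at season end, no predators).
#   migration: removal closure, set only where the printed EE exceeds what
#     predation plus catch explain by >1% (benthos/bacteria removed with the
#     sediment at draining); derived, not printed.
#   fate fractions: water-column groups send 0.316147 of their detritus flow to
#     the water pool (fitted to the printed water-detritus EE 0.716);
#     sediment-associated groups (Mollusca, Oligochaeta, Chironomidae,
#     sediment bacteria) route 100% to the sediment pool; the water pool
#     passes 0.199697 of its surplus to the sediment pool (fitted to the
#     printed inter-pool flow 171.6098); sediment-pool surplus accumulates.
name,category,biomass,pb,qb,ee,gs,catch,import,ba,migration,surplus_disposition,fate_Feed,fate_Precipitation,fate_Detritus (water),fate_Detritus (sediment)
C. idellus,consumer,240.81,1.64,4.32,0.985,0.41,389.004474,0,0,0,export,0,0,0.316147,0.683853
H. molitrix,consumer,46.47,1.31,6.18,0.989,0.2,60.206067,0,0,0,export,0,0,0.316147,0.683853
A. nobilis,consumer,95.77,1.7,7.21,0.996,0.2,162.157764,0,0,0,export,0,0,0.316147,0.683853
C. auratus,consumer,8.71,1.45,4.88,0.968,0.2,12.225356,0,0,0,export,0,0,0.316147,0.683853
Protozoa,consumer,0.592,62.87,337.4,0.75,0.65,0,0,0,0,export,0,0,0.316147,0.683853
Rotifera,consumer,0.738,127.4,548,0.981,0.65,0,0,0,0,export,0,0,0.316147,0.683853
Cladocera,consumer,0.598,203.4,797,0.762,0.65,0,0,0,0,export,0,0,0.316147,0.683853
Copepoda,consumer,0.652,250.8,816.7,0.382,0.65,0,0,0,0,export,0,0,0.316147,0.683853
Mollusca,consumer,20.6,4.32,33.84,0.242,0.7,0,0,0,21.536064,export,0,0,0,1
Oligochaeta,consumer,0.1702,5.27,263.5,0.713,0.2,0,0,0,0.086966,export,0,0,0,1
Chironomidae,consumer,0.1362,4.47,223.5,0.79,0.2,0,0,0,0.01341,export,0,0,0,1
Bacteria (water),consumer,5.19,121.3,327.4,0.679,0.4,0,0,0,5.685662,export,0,0,0.316147,0.683853
Bacteria (sediment),consumer,13.32,201.5,503.8,0.14,0.4,0,0,0,16.145843,export,0,0,0,1
Phytoplankton,producer,25.44,341,0,0.213,0,0,0,0,0,export,0,0,0.316147,0.683853
Feed,detritus,1.372,0,0,0.978,0,0,1351,0,0,export,0,0,0.316147,0.683853
Precipitation,detritus,0.0104,0,0,0.382,0,0,6.24,0,0,export,0,0,0.316147,0.683853
Detritus (water),detritus,2.268,0,0,0.716,0,0,0,0,0,export,0,0,0,0.199697
Detritus (sediment),detritus,2.412,0,0,0.528,0,0,0,0,0,accumulation,0,0,0,0
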