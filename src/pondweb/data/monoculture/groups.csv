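# Monoculture grass-carp pond, 16 functional groups; all rates per 300-day season.
# Biomass, P/B, Q/B, EE, imports: published basic-parameter table values.
# Resolved or derived cells:
#   Bacteria (water) P/B = 164.3 (the printed 114.3 is inconsistent with the
#     system respiration and detritus-flow totals; 164.3 restores both).
#   gs: grass carp 0.41, zooplankton 0.65, Mollusca 0.7, bacteria 0.4 per the
#     stated assimilation conventions; other fish 0.2 (carnivore default);
#     Oligochaeta/Chironomidae 0.2, derived from the flow-to-detritus identity.
#   catch = P*EE for fish (fully harvested at season end, no predators).
#   migration: removal closure, set only where the printed EE exceeds what
#     predation plus catch explain by >1% (benthos/bacteria removed with the
#     sediment at draining); derived, not printed.
#   fate fractions: water-column groups send 0.284462 of their detritus flow to
#     the water pool (fitted to the printed water-detritus EE 0.899);
#     sediment-associated groups (Mollusca, Oligochaeta, Chironomidae,
#     sediment bacteria) route 100% to the sediment pool; the water pool
#     passes 0.200517 of its surplus to the sediment pool (fitted to the
#     printed inter-pool flow 62.0107); sediment-pool surplus accumulates.
name,category,biomass,pb,qb,ee,gs,catch,import,ba,migration,surplus_disposition,fate_Feed,fate_Precipitation,fate_Detritus (water),fate_Detritus (sediment)
C. idellus,consumer,358.1,1.59,4.21,0.96,0.41,546.60384,0,0,0,export,0,0,0.284462,0.715538
H. molitrix,consumer,32.27,1.81,6.71,0.953,0.2,55.663491,0,0,0,export,0,0,0.284462,0.715538
Protozoa,consumer,0.628,82.31,537.6,0.767,0.65,0,0,0,0,export,0,0,0.284462,0.715538
Rotifera,consumer,1.882,77.39,435.9,0.947,0.65,0,0,0,0,export,0,0,0.284462,0.715538
Cladocera,consumer,1.267,108.5,670.5,0.91,0.65,0,0,0,0,export,0,0,0.284462,0.715538
Copepoda,consumer,1.393,198.3,665.7,0.167,0.65,0,0,0,1.311398,export,0,0,0.284462,0.715538
Mollusca,consumer,17.09,1.86,14.88,0.17,0.7,0,0,0,5.403858,export,0,0,0,1
Oligochaeta,consumer,0.124,4.41,220.5,0.226,0.2,0,0,0,0.123586,export,0,0,0,1
Chironomidae,consumer,0.103,8.65,432.5,0.042,0.2,0,0,0,0.03742,export,0,0,0,1
Bacteria (water),consumer,5.51,164.3,408.5,0.632,0.4,0,0,0,0,export,0,0,0.284462,0.715538
Bacteria (sediment),consumer,11.75,178.4,545.9,0.158,0.4,0,0,0,12.149015,export,0,0,0,1
Phytoplankton,producer,24.84,343.8,0,0.23,0,0,0,0,21.410571,export,0,0,0.284462,0.715538
Feed,detritus,1.472,0,0,0.941,0,0,1612,0,0,export,0,0,0.284462,0.715538
Precipitation,detritus,0.0104,0,0,0.523,0,0,6.24,0,0,export,0,0,0.284462,0.715538
Detritus (water),detritus,2.615,0,0,0.899,0,0,0,0,0,export,0,0,0,0.200517
Detritus (sediment),detritus,2.875,0,0,0.504,0,0,0,0,0,accumulation,0,0,0,0
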