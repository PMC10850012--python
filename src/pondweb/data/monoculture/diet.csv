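# Diet composition, prey rows x predator columns, published diet table.
# Rotifera and Cladocera columns renormalized from printed sums 1.0005 and
# 0.9997 to exactly 1.
prey\predator,C. idellus,H. molitrix,Protozoa,Rotifera,Cladocera,Copepoda,Mollusca,Oligochaeta,Chironomidae,Bacteria (water),Bacteria (sediment),Phytoplankton,Feed,Precipitation,Detritus (water),Detritus (sediment)
C. idellus,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H. molitrix,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Protozoa,0,0.006,0,0.00299850074963,0.0190057017105,0.021,0,0,0,0,0,0,0,0,0,0
Rotifera,0.008,0.011,0,0,0.0410123036911,0.095,0,0,0,0,0,0,0,0,0,0
Cladocera,0.008,0.012,0,0,0,0.119,0,0,0,0,0,0,0,0,0,0
Copepoda,0.027,0.019,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Mollusca,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Oligochaeta,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Chironomidae,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Bacteria (water),0.014,0.031,0.301,0.228885557221,0.129038711613,0.12,0.085,0.107,0.097,0,0,0,0,0,0,0
Bacteria (sediment),0,0,0.141,0.0729635182409,0.0910273081925,0.039,0.297,0.335,0.301,0,0,0,0,0,0,0
Phytoplankton,0.129,0.661,0.337,0.512743628186,0.592177653296,0.457,0.446,0.405,0.436,0,0,0,0,0,0,0
Feed,0.701,0.101,0.001,0.00149925037481,0.00170051015305,0.002,0.001,0.001,0.001,0.05,0.05,0,0,0,0,0
Precipitation,0,0,0.001,0.000999500249875,0.00100030009003,0.001,0.001,0.001,0.001,0,0,0,0,0,0,0
Detritus (water),0.113,0.159,0.211,0.170914542729,0.117035110533,0.091,0.043,0.041,0.051,0.95,0,0,0,0,0,0
Detritus (sediment),0,0,0.008,0.00899550224888,0.00800240072022,0.055,0.127,0.11,0.113,0,0.95,0,0,0,0,0
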