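# Default species property table for the pahfire pipeline.
# One row per species. All values are representative defaults intended to make
# the pipeline run out of the box; every column is overridable per run by
# supplying a replacement table with the same schema.
#   teq        : toxic equivalency relative to benzo[a]pyrene (BAP = 1.0).
#                Parent values follow the widely used Nisbet/LaGoy-style
#                potency-equivalence scheme; nitro/dinitro product values follow
#                regulatory potency-equivalence factors (OEHHA-style). These are
#                configuration, not assertions of measured truth.
#   k_oh       : gas-phase OH rate constant, cm3 molecule-1 s-1 (representative
#                literature magnitudes).
#   k_no3      : gas-phase NO3 rate constant, cm3 molecule-1 s-1 (effective
#                first-order nitration pathway; desk-scale defaults).
#   gamma_o3   : dimensionless heterogeneous O3 reactive-uptake parameter.
#   pplfer_*   : Abraham-style solute descriptors (E, S, A, B, L) used by the
#                poly-parameter linear free energy partitioning scheme.
#   parent     : for NPAH/DNPAH degradation products, the parent PAH whose
#                diagnosed product field supplies their concentration.
abbreviation,full_name,ring_count,species_class,parent,molecular_weight,teq,k_oh,k_no3,gamma_o3,pplfer_e,pplfer_s,pplfer_a,pplfer_b,pplfer_l
NAP,naphthalene,2,parent,,128.17,0.001,2.3e-11,3.6e-17,1.0e-3,1.34,0.92,0.0,0.20,5.16
ACY,acenaphthylene,3,parent,,152.19,0.001,1.1e-10,1.0e-16,1.0e-3,1.75,1.14,0.0,0.26,5.77
ACE,acenaphthene,3,parent,,154.21,0.001,1.0e-10,1.0e-16,1.0e-3,1.60,1.05,0.0,0.22,6.47
FLO,fluorene,3,parent,,166.22,0.001,1.3e-11,1.0e-16,1.0e-3,1.59,1.06,0.0,0.25,6.92
PHEN,phenanthrene,3,parent,,178.23,0.001,2.7e-11,1.2e-16,1.0e-3,2.06,1.29,0.0,0.29,7.63
ANT,anthracene,3,parent,,178.23,0.010,1.3e-10,1.7e-16,1.0e-3,2.29,1.34,0.0,0.28,7.57
FLA,fluoranthene,4,parent,,202.25,0.001,5.0e-11,4.0e-16,2.0e-3,2.38,1.55,0.0,0.24,8.83
PYR,pyrene,4,parent,,202.25,0.001,5.0e-11,1.0e-15,2.0e-3,2.81,1.71,0.0,0.28,8.83
BAA,benzo[a]anthracene,4,parent,,228.29,0.100,5.0e-11,5.0e-16,3.0e-3,2.99,1.70,0.0,0.35,10.29
CHR,chrysene,4,parent,,228.29,0.010,5.0e-11,5.0e-16,3.0e-3,3.03,1.73,0.0,0.36,10.30
BBF,benzo[b]fluoranthene,5,parent,,252.31,0.100,5.0e-11,5.0e-16,5.0e-3,3.19,1.82,0.0,0.40,11.60
BKF,benzo[k]fluoranthene,5,parent,,252.31,0.100,5.0e-11,5.0e-16,5.0e-3,3.19,1.91,0.0,0.33,11.60
BAP,benzo[a]pyrene,5,parent,,252.31,1.000,5.0e-11,5.0e-16,5.0e-3,3.63,1.98,0.0,0.44,11.70
BGHIP,"benzo[g,h,i]perylene",6,parent,,276.33,0.010,5.0e-11,5.0e-16,5.0e-3,4.07,1.90,0.0,0.45,12.60
ICDP,"indeno[1,2,3-c,d]pyrene",6,parent,,276.33,0.100,5.0e-11,5.0e-16,5.0e-3,3.90,1.90,0.0,0.50,12.80
DAHA,"dibenz[a,h]anthracene",5,parent,,278.35,5.000,5.0e-11,5.0e-16,5.0e-3,4.00,2.04,0.0,0.50,12.60
1NPYR,1-nitropyrene,4,NPAH,PYR,247.25,0.100,3.0e-11,0.0,2.0e-3,3.00,2.00,0.0,0.30,9.50
4NPYR,4-nitropyrene,4,NPAH,PYR,247.25,0.100,3.0e-11,0.0,2.0e-3,3.00,2.00,0.0,0.30,9.50
2NFLO,2-nitrofluorene,3,NPAH,FLO,211.22,0.010,3.0e-11,0.0,1.0e-3,1.90,1.60,0.0,0.30,7.60
6NCHR,6-nitrochrysene,4,NPAH,CHR,273.29,10.000,3.0e-11,0.0,3.0e-3,3.20,2.10,0.0,0.40,11.00
16DNPYR,"1,6-dinitropyrene",4,DNPAH,PYR,292.25,10.000,1.0e-11,0.0,2.0e-3,3.20,2.30,0.0,0.40,10.20
18DNPYR,"1,8-dinitropyrene",4,DNPAH,PYR,292.25,1.100,1.0e-11,0.0,2.0e-3,3.20,2.30,0.0,0.40,10.20
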