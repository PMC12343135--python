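# Per-stage myofibril morphometric defaults for Drosophila indirect
# flight muscle (IFM) development.  Band widths (um), thick-filament
# counts and lattice spacings (nm) are published stage averages from
# TEM and dSTORM measurements; thick/thin filament lengths derive from
# these via the band-width identities.  L_sarcomere at the mature stage
# (24h_AE) is the exactly consistent published set; at the three pupal
# stages it is an estimate consistent with the reported growth curves
# and is marked by the trailing `L_s_estimated` flag.
stage,L_sarcomere_um,W_I_band_um,W_H_zone_um,W_Z_disc_um,n_thick,spacing_nm,L_s_estimated
36h_APF,2.35,0.71,1.47,0.24,23,53,1
48h_APF,2.45,0.51,1.61,0.14,32,47,1
72h_APF,3.00,0.43,0.438,0.098,134,47,1
24h_AE,3.40,0.16,0.134,0.094,846,48,0
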