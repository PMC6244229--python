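measure,predictor,beta,lo,hi
AF_RA,URB,-0.06,-0.08,-0.04
AF_J,URB,-0.04,-0.06,-0.02
AS_RA,FA,0.34,0.04,0.63
AS_RA,AG,-0.22,-0.39,-0.04
AS_J,FA,0.24,0.17,0.32
AS_J,FPD,0.12,0.08,0.16
AS_J,AG,-0.30,-0.35,-0.25
FG_RA,AG,0.13,0.08,0.18
FG_RA,FCI,0.04,0.002,0.08
FG_RA,FPD,-0.15,-0.19,-0.11
FG_RA,URB,-0.14,-0.18,-0.11
FG_SR,FA,0.29,0.06,0.52
FG_SR,AG,0.20,0.05,0.35
FG_J,FA,-0.06,-0.09,-0.02
FG_J,FPD,-0.03,-0.05,-0.01
FG_J,FCI,-0.04,-0.07,-0.02
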