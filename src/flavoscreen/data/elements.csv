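element,nominal_offset,mass,abundance
C,0,12.0,0.9893
C,1,13.00335483507,0.0107
H,0,1.00782503207,0.999885
H,1,2.01410177785,0.000115
N,0,14.00307400443,0.99636
N,1,15.00010889888,0.00364
O,0,15.99491461957,0.99757
O,1,16.99913175650,0.00038
O,2,17.99915961286,0.00205
S,0,31.97207117440,0.9499
S,1,32.97145890980,0.0075
S,2,33.96786700400,0.0425
S,4,35.96708071000,0.0001
P,0,30.97376199842,1.0
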