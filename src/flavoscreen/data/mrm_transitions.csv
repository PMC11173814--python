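analyte,rt_min,mode,parent_ion,product_ion,role,dp_v,ce_ev
Glycitin,6.24,[M+H]+,447,385,qualitative,39,26
Glycitin,6.24,[M+H]+,447,285,quantitative,39,28
Genistin,6.63,[M+H]+,433,271,quantitative,52,41
Daidzein,3.12,[M-H]-,253,132,quantitative,-66,-46
Daidzein,3.12,[M-H]-,253,91,qualitative,-66,-53
Glycitein,3.20,[M-H]-,283,268,quantitative,-50,-24
Glycitein,3.20,[M-H]-,283,240,qualitative,-50,-34
Genistein,3.49,[M-H]-,269,159,qualitative,-65,-34
Genistein,3.49,[M-H]-,269,133,quantitative,-65,-42
Formononetin,4.20,[M-H]-,267,252,quantitative,-60,-29
Formononetin,4.20,[M-H]-,267,223,qualitative,-60,-45
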