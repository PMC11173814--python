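analyte,formula,slope,intercept,r_squared,range_low_ng_ml,range_high_ng_ml,lod_ng_ml
Glycitin,C22H22O10,66.98,328.49,0.9998,9.6,960,4.80
Genistin,C21H20O10,88.328,66.149,0.9999,9.3,930,2.33
Daidzein,C15H10O4,135.86,81.416,0.9998,2.55,255,1.02
Glycitein,C16H12O5,782,-146,0.9999,1.02,102,0.25
Genistein,C15H10O5,207.22,-11.976,0.9999,4.85,970,2.43
Formononetin,C16H12O4,620.1,323.56,0.9998,0.95,47.5,0.48
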