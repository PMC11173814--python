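batch,analyte,content_ug_g
210117,Glycitin,6.21
210117,Genistin,0.63
210117,Daidzein,107.55
210117,Glycitein,29.06
210117,Genistein,191.38
210117,Formononetin,0.12
230110,Glycitin,8.75
230110,Genistin,0.95
230110,Daidzein,69.08
230110,Glycitein,31.71
230110,Genistein,157.57
230110,Formononetin,0.18
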