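number,name,rt_min,esi_mode_printed,formula,theoretical_mz,experimental_mz,error_ppm_printed,fragments,subclass
1,Glycitin,10.56,[M+H]+,C22H22O10,447.1286,447.1297,2.6,285.0764;270.0562,isoflavone_glycoside
2,Genistin,11.29,[M+H]+,C21H20O10,433.1129,433.1135,1.3,271.0595;215.0702;159.0428,isoflavone_glycoside
3,Acetyldaidzin,11.57,[M+H]+,C23H22O10,459.1286,459.1289,0.7,255.0652;227.0679;199.0759,isoflavone_glycoside
4,Unknown,11.81,[M-H]-,C16H12O6,299.0561,299.0564,0.9,284.0343;256.0352;239.0336;212.0489;200.0487;148.0142,unknown
5,Unknown,12.27,[M-H]-,C15H10O6,285.0405,285.0413,3,241.0523;213.0551;185.0605;171.0589;156.0625,unknown
6,Unknown,12.59,[M-H]-,C16H12O6,299.0561,299.0565,1.1,284.0339;256.0383;231.0223;210.9797;192.9927;183.0437;166.9822;154.9918,unknown
7,Scutellarein,13.23,[M-H]-,C15H10O6,285.0405,285.0403,-0.5,257.0460;241.0492;229.0489;212.0505,flavone
8,Daidzein,13.4,[M-H]-,C15H10O4,253.0506,253.0507,0.3,224.0484;208.0539;196.0523;180.0589;133.0297;91.0197,isoflavone
9,Unknown,13.42,[M-H]-,C19H16O7,355.0823,355.0822,-0.4,314.9869;295.0048;253.0489;231.0052;211.0426;135.0046,unknown
10,Glycitein,13.66,[M-H]-,C16H12O5,283.0612,283.0616,1.6,268.0375;240.0425;211.0388;196.0531;184.0518,isoflavone
11,Unknown,13.82,[M+H]+,C17H14O6,315.0863,315.0868,1.5,297.0441;255.0649,unknown
12,Unknown,13.99,[M+H]+,C19H16O7,357.0969,357.0966,-0.7,311.0981;255.0647;237.0502;199.0781;181.0615;137.0278,unknown
13,Luteolin,14.11,[M-H]-,C15H10O6,285.0405,285.0407,0.9,241.0488;213.0559;187.0397;157.0663;145.0631;123.0094;95.0146,flavone
14,Genistein,14.2,[M-H]+,C15H10O5,269.0456,269.0458,0.9,241.0527;224.0492;133.0301;107.0149,isoflavone
15,Unknown,14.21,[M-H]-,C16H12O6,299.0561,299.0563,0.5,284.0358;255.0350;183.0465;137.0032,unknown
16,Kaempferol,14.63,[M-H]-,C15H10O6,285.0405,285.0410,1.8,257.0466;229.0519;185.0595;149.0255,flavonol
17,Formononetin,15.29,[M-H]-,C16H12O4,267.0663,267.0665,1,252.0431;223.0404;208.0526;132.0238,isoflavone
18,Neobavaisoflavone,16.69,[M-H]-,C20H18O4,321.1132,321.1135,0.9,252.0434;223.0396;195.0456,isoflavone
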