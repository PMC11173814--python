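subclass,label,formula,polarity
isoflavone,"0,3B0",C8H5O2,negative
isoflavone,"0,4A0",C6H3O2,negative
flavone,"0,3B0",C8H5O2,negative
flavonol,"0,3B0",C8H5O2,negative
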