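(((Dmel:0.625,Dpse:0.625)sophAB:0.25,Dwil:0.875)soph:0.125,((Dmoj:0.65,Dvir:0.65)drosAB:0.25,Dgri:0.9)dros:0.1)root;
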