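(Chromerida,((Gregarinia,Marosporida),(Nephromycida,(Cryptosporidia,((Sarcocystidae,Eimeriidae),(Haemosporida,Piroplasmida))))));
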