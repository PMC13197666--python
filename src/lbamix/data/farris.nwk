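(((A:0.15,B:0.2)AB:0.8,(E:0.2,F:0.25)EF:1.0)ABEF:0.05,(C:0.1,D:0.12)CD:0.15,((G:0.08,H:0.1)GH:0.06,(I:0.09,J:0.12)IJ:0.07)GHIJ:0.1);
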