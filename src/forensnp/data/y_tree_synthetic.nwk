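((Y-A1,Y-A2)Y-A,(Y-C1,Y-C2)Y-C,((Y-E1a)Y-E1,Y-E2)Y-E,(Y-H1,Y-H2)Y-H,((Y-O1a)Y-O1)Y-O,((Y-Q1a)Y-Q1)Y-Q,((Y-R1a)Y-R1,Y-R2)Y-R)YROOT;
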