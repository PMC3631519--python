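((mt-A1,mt-A2)mt-A,(mt-C1,mt-C2)mt-C,((mt-E1a)mt-E1,mt-E2)mt-E,(mt-H1,mt-H2)mt-H,((mt-O1a)mt-O1)mt-O,((mt-Q1a)mt-Q1)mt-Q,((mt-R1a)mt-R1,mt-R2)mt-R)mtROOT;
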