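cdc2	I:1150-1450
SPNCRNA.01	II:1200-1500
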