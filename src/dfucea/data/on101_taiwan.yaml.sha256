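9462d34b4f596a37c7b10933e69f36bd838bf961b9f6fb0cbb2f5553eb4c52de
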