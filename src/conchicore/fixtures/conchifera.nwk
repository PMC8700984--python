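(Nautilus,((Lottia,Euhadra)Gastropoda,(Crassostrea,Pinctada)Bivalvia)Gastropoda_Bivalvia)Ancestral_Conchiferan;
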