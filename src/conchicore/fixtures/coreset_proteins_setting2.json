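{
  "description": "Relaxed-setting (e-value only) reciprocal-search outcome for the named shell matrix proteins, as a presence matrix over the five compared conchiferans (transcribed reference values).",
  "setting": "setting2",
  "focal": "Nautilus",
  "species": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
  "proteins": {
    "Pif/BMSP-like protein": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "CD109 Antigen protein": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "Tyrosinase": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "EGF-ZP domain-containing protein": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Chitinase": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Peroxidase": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Kunitz domain-containing protein": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "LOTGIDRAFT_169029 (Chitin-binding domain-containing protein)": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Nucleobindin-like protein": ["Nautilus", "Lottia"],
    "Phospholipase A2-like protein": ["Nautilus", "Lottia"]
  }
}
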