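{
  "description": "Species-level domain presence of the twelve shared shell-matrix-protein domain features across the five compared conchiferans (transcribed reference values).",
  "focal": "Nautilus",
  "species": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
  "domains": {
    "A2M_comp": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "A2M_recep": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "ChtBD2": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "Signal Peptide": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "Tyrosinase": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "VWA": ["Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra"],
    "An_Peroxidase": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Glyco_18": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "ZP": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "EGF": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "KU": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"],
    "Thiol-ester_cl": ["Nautilus", "Crassostrea", "Pinctada", "Lottia"]
  }
}
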