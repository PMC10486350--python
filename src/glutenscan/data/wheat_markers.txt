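# Curated wheat-specific marker peptides for contamination screening.
# DVSPGCRPITVSPGTR is the canonical HMW-glutenin tryptic marker; the
# remaining entries are wheat-specific peptides observed in barley-beer
# surveys (CM17 protein Q41540, peroxiredoxin Q6W8Q2, small heat-shock
# protein A0A3B6JKI7). Replace or extend with a matrix-specific panel
# for regulatory work.
DVSPGCRPITVSPGTR
RIEMPGPPY
ACRIEMPGPPY
VEEQACRIEMPGPPY
DAEGQLPSRT
PDEKDAEGQLPSR
VEVEDGNILQISGERK
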