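# Species registry for Cas12a/Cas13d array design.
#
# Plain-text, editable. Each section is one species; `alias` adds a short
# lookup key. `full_separator` is the natural AT-rich pre-processing repeat
# fragment excised during crRNA maturation; `default_synseparator` is the
# short 3'-derived synthetic insulator placed upstream of every repeat.
#
# Provenance matters: the printed literature gives the synSeparators (AAAT
# for Lachnospiraceae bacterium, TTTT for Acidaminococcus sp.) and the
# mature repeats are standard literature sequences. The exact 16-nt full
# separator sequences are published only in supplementary material; the
# entries below are SYNTHETIC placeholders constrained to the documented
# properties (5' GTYTA motif, AT-rich, 3' terminus equal to the
# synSeparator) and MUST be overridden with the published sequences for any
# analysis that depends on the full separator itself.

[Lachnospiraceae bacterium]
alias = Lb
mature_repeat = AATTTCTACTAAGTGTAGAT
full_separator = GTCTAAGAACTTAAAT
default_synseparator = AAAT
provenance = mature repeat: standard LbCas12a literature; full separator: SYNTHETIC placeholder (GTYTA 5' motif, AT-rich, AAAT 3' end); synSeparator AAAT: printed

[Acidaminococcus species]
alias = As
mature_repeat = TAATTTCTACTCTTGTAGAT
full_separator = GTTTAAGAACTATTTT
default_synseparator = TTTT
provenance = mature repeat: standard AsCas12a literature; full separator: SYNTHETIC placeholder (GTYTA 5' motif, AT-rich, TTTT 3' end); synSeparator TTTT: printed
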