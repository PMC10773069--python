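chrM	65	71
chrM	302	316
chrM	512	525
chrM	5891	5892
chrM	3105	3107
chrM	12417	12425
chrM	16181	16194
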