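# Known mitochondrial micropeptide ORFs to exclude from "unannotated" counts.
# User-editable sidecar: fill in aa_sequence and/or reference coordinates for
# your genome build (the discovery filter matches by exact peptide string or
# by coordinate identity, whichever is provided).  Blank fields = unknown.
name	aa_sequence	start	end	strand
Humanin
SHLP1
SHLP2
SHLP3
SHLP4
SHLP5
SHLP6
MOTS-c
gau
SHMOOSE
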