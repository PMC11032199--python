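# Catalytic-site column spec for the SYNTHETIC 264-column Pkinase-like model
# emitted by stkflux.synthetic_data.  These columns are properties of that
# generated model only; for a real Pfam PF00069 release, derive the columns by
# aligning a reference kinase with experimentally known catalytic residues
# (e.g. human PKA C-alpha: K72, D166, D184) against the release's HMM and
# reading off the matched model columns, then write them into a spec file like
# this one.
model_length: 264
pos_K: 30
pos_D1: 125
pos_D2: 143
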