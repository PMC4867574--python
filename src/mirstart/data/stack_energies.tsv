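# Nearest-neighbor helix stacking free energies, dG37 in kcal/mol.
# Key: pair of adjacent base pairs read 5'->3' on the top strand;
# "XY WZ" means top-strand X paired to Y stacked on top-strand W
# paired to Z.  Watson-Crick x Watson-Crick entries are the standard
# Turner/Xia nearest-neighbor values; wobble(GU)-containing entries
# are conservative negative approximations.
AU	AU	-0.93
AU	UA	-1.10
AU	GC	-2.24
AU	CG	-2.08
UA	AU	-1.33
UA	UA	-0.93
UA	GC	-2.35
UA	CG	-2.11
GC	AU	-2.11
GC	UA	-2.08
GC	GC	-3.26
GC	CG	-2.36
CG	AU	-2.35
CG	UA	-2.24
CG	GC	-3.42
CG	CG	-3.26
GU	GU	-0.50
UG	UG	-0.50
GU	UG	-0.60
UG	GU	-0.60
GU	AU	-1.30
UA	UG	-1.30
GU	UA	-1.20
AU	UG	-1.20
GU	GC	-2.10
CG	UG	-2.10
GU	CG	-1.90
GC	UG	-1.90
UG	AU	-1.00
UA	GU	-1.00
UG	UA	-1.10
AU	GU	-1.10
UG	GC	-1.80
CG	GU	-1.80
UG	CG	-1.50
GC	GU	-1.50
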