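# Restriction enzyme library for CAPS/dCAPS design: name <TAB> recognition site
# (5'->3', IUPAC ambiguity codes allowed). A small curated set of common
# six-cutters; user-extensible via the same two-column format.
AflIII	ACRYGT
AgeI	ACCGGT
ApoI	RAATTY
AvrII	CCTAGG
BamHI	GGATCC
BglII	AGATCT
BsrGI	TGTACA
DraI	TTTAAA
EcoRI	GAATTC
EcoRV	GATATC
HincII	GTYRAC
HindIII	AAGCTT
HpaI	GTTAAC
KpnI	GGTACC
MfeI	CAATTG
MluI	ACGCGT
NcoI	CCATGG
NdeI	CATATG
NheI	GCTAGC
NsiI	ATGCAT
PstI	CTGCAG
SacI	GAGCTC
SalI	GTCGAC
ScaI	AGTACT
SmaI	CCCGGG
SnaBI	TACGTA
SpeI	ACTAGT
SphI	GCATGC
SspI	AATATT
StuI	AGGCCT
XbaI	TCTAGA
XhoI	CTCGAG
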