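res_name	chi1	chi2	chi3	chi4	probability
ARG	-60	180	180	180	0.18
ARG	180	180	180	180	0.12
ARG	-60	180	-60	180	0.10
ARG	-60	-60	180	180	0.08
ARG	60	180	180	180	0.05
LYS	-60	180	180	180	0.25
LYS	180	180	180	180	0.18
LYS	-60	-60	180	180	0.08
GLN	-60	180	-25		0.22
GLN	-60	-60	-40		0.12
GLN	180	65	20		0.10
GLN	180	180	20		0.09
GLU	-60	180	-10		0.24
GLU	180	180	0		0.13
GLU	-60	-60	-40		0.12
MET	-60	180	-70		0.20
MET	-60	180	70		0.18
MET	180	180	75		0.10
ASP	-60	-15			0.30
ASP	180	0			0.21
ASP	60	10			0.08
ASN	-60	-20			0.30
ASN	180	30			0.16
ASN	60	20			0.09
ILE	-60	170			0.55
ILE	-60	-60			0.15
ILE	180	170			0.12
LEU	-60	180			0.55
LEU	180	65			0.28
HIS	-60	-75			0.26
HIS	-60	80			0.20
HIS	180	-165			0.14
PHE	-60	90			0.44
PHE	180	80			0.33
PHE	60	90			0.10
TYR	-60	90			0.44
TYR	180	80			0.33
TYR	60	90			0.10
TRP	-60	95			0.30
TRP	180	-105			0.20
TRP	-60	-5			0.15
PRO	-25	40			0.55
PRO	25	-35			0.40
SER	60				0.45
SER	-60				0.30
SER	180				0.22
THR	60				0.50
THR	180				0.35
THR	-60				0.10
CYS	-60				0.50
CYS	180				0.30
CYS	60				0.15
VAL	180				0.70
VAL	-60				0.20
VAL	60				0.08
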