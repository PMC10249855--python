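# Political grouping by 2020 US presidential election winner per state,
# 50 states + DC (v1). Democratic = Biden carried the state, Republican =
# Trump carried it. Analyses that weigh senate results or party
# registration differently can supply a replacement two-column CSV with
# the same header.
state,group
AK,Republican
AL,Republican
AR,Republican
AZ,Democratic
CA,Democratic
CO,Democratic
CT,Democratic
DC,Democratic
DE,Democratic
FL,Republican
GA,Democratic
HI,Democratic
IA,Republican
ID,Republican
IL,Democratic
IN,Republican
KS,Republican
KY,Republican
LA,Republican
MA,Democratic
MD,Democratic
ME,Democratic
MI,Democratic
MN,Democratic
MO,Republican
MS,Republican
MT,Republican
NC,Republican
ND,Republican
NE,Republican
NH,Democratic
NJ,Democratic
NM,Democratic
NV,Democratic
NY,Democratic
OH,Republican
OK,Republican
OR,Democratic
PA,Democratic
RI,Democratic
SC,Republican
SD,Republican
TN,Republican
TX,Republican
UT,Republican
VA,Democratic
VT,Democratic
WA,Democratic
WI,Democratic
WV,Republican
WY,Republican
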