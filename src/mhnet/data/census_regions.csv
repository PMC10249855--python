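# US Census Bureau four-region grouping, 50 states + DC (v1).
# Regions: midwest, northeast, south, west. DC is assigned to the south
# (Census places it in the South Atlantic division); drop the DC row to
# run a 50-state analysis.
state,group
AK,west
AL,south
AR,south
AZ,west
CA,west
CO,west
CT,northeast
DC,south
DE,south
FL,south
GA,south
HI,west
IA,midwest
ID,west
IL,midwest
IN,midwest
KS,midwest
KY,south
LA,south
MA,northeast
MD,south
ME,northeast
MI,midwest
MN,midwest
MO,midwest
MS,south
MT,west
NC,south
ND,midwest
NE,midwest
NH,northeast
NJ,northeast
NM,west
NV,west
NY,northeast
OH,midwest
OK,south
OR,west
PA,northeast
RI,northeast
SC,south
SD,midwest
TN,south
TX,south
UT,west
VA,south
VT,northeast
WA,west
WI,midwest
WV,south
WY,west
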