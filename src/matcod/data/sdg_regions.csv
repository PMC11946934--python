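country,region
AUS,Australia and New Zealand
NZL,Australia and New Zealand
AFG,Central Asia and Southern Asia
BGD,Central Asia and Southern Asia
BTN,Central Asia and Southern Asia
IND,Central Asia and Southern Asia
IRN,Central Asia and Southern Asia
KAZ,Central Asia and Southern Asia
KGZ,Central Asia and Southern Asia
LKA,Central Asia and Southern Asia
MDV,Central Asia and Southern Asia
NPL,Central Asia and Southern Asia
PAK,Central Asia and Southern Asia
TJK,Central Asia and Southern Asia
TKM,Central Asia and Southern Asia
UZB,Central Asia and Southern Asia
BRN,Eastern Asia and South-eastern Asia
CHN,Eastern Asia and South-eastern Asia
IDN,Eastern Asia and South-eastern Asia
JPN,Eastern Asia and South-eastern Asia
KHM,Eastern Asia and South-eastern Asia
KOR,Eastern Asia and South-eastern Asia
LAO,Eastern Asia and South-eastern Asia
MMR,Eastern Asia and South-eastern Asia
MNG,Eastern Asia and South-eastern Asia
MYS,Eastern Asia and South-eastern Asia
PHL,Eastern Asia and South-eastern Asia
PRK,Eastern Asia and South-eastern Asia
SGP,Eastern Asia and South-eastern Asia
THA,Eastern Asia and South-eastern Asia
TLS,Eastern Asia and South-eastern Asia
VNM,Eastern Asia and South-eastern Asia
ARG,Latin America and the Caribbean
ATG,Latin America and the Caribbean
BHS,Latin America and the Caribbean
BLZ,Latin America and the Caribbean
BOL,Latin America and the Caribbean
BRA,Latin America and the Caribbean
BRB,Latin America and the Caribbean
CHL,Latin America and the Caribbean
COL,Latin America and the Caribbean
CRI,Latin America and the Caribbean
CUB,Latin America and the Caribbean
DOM,Latin America and the Caribbean
ECU,Latin America and the Caribbean
GRD,Latin America and the Caribbean
GTM,Latin America and the Caribbean
GUY,Latin America and the Caribbean
HND,Latin America and the Caribbean
HTI,Latin America and the Caribbean
JAM,Latin America and the Caribbean
LCA,Latin America and the Caribbean
MEX,Latin America and the Caribbean
NIC,Latin America and the Caribbean
PAN,Latin America and the Caribbean
PER,Latin America and the Caribbean
PRI,Latin America and the Caribbean
PRY,Latin America and the Caribbean
SLV,Latin America and the Caribbean
SUR,Latin America and the Caribbean
TTO,Latin America and the Caribbean
URY,Latin America and the Caribbean
VCT,Latin America and the Caribbean
VEN,Latin America and the Caribbean
AUT,Northern America and Europe
BEL,Northern America and Europe
BGR,Northern America and Europe
BIH,Northern America and Europe
BLR,Northern America and Europe
CAN,Northern America and Europe
CHE,Northern America and Europe
CZE,Northern America and Europe
DEU,Northern America and Europe
DNK,Northern America and Europe
ESP,Northern America and Europe
EST,Northern America and Europe
FIN,Northern America and Europe
FRA,Northern America and Europe
GBR,Northern America and Europe
GRC,Northern America and Europe
HRV,Northern America and Europe
HUN,Northern America and Europe
IRL,Northern America and Europe
ISL,Northern America and Europe
ITA,Northern America and Europe
LTU,Northern America and Europe
LUX,Northern America and Europe
LVA,Northern America and Europe
MDA,Northern America and Europe
MKD,Northern America and Europe
MLT,Northern America and Europe
MNE,Northern America and Europe
NLD,Northern America and Europe
NOR,Northern America and Europe
POL,Northern America and Europe
PRT,Northern America and Europe
ROU,Northern America and Europe
RUS,Northern America and Europe
SRB,Northern America and Europe
SVK,Northern America and Europe
SVN,Northern America and Europe
SWE,Northern America and Europe
UKR,Northern America and Europe
USA,Northern America and Europe
FJI,Oceania excluding Australia and New Zealand
PNG,Oceania excluding Australia and New Zealand
SLB,Oceania excluding Australia and New Zealand
TON,Oceania excluding Australia and New Zealand
VUT,Oceania excluding Australia and New Zealand
WSM,Oceania excluding Australia and New Zealand
AGO,Sub-Saharan Africa
BDI,Sub-Saharan Africa
BEN,Sub-Saharan Africa
BFA,Sub-Saharan Africa
BWA,Sub-Saharan Africa
CAF,Sub-Saharan Africa
CIV,Sub-Saharan Africa
CMR,Sub-Saharan Africa
COD,Sub-Saharan Africa
COG,Sub-Saharan Africa
CPV,Sub-Saharan Africa
ERI,Sub-Saharan Africa
ETH,Sub-Saharan Africa
GAB,Sub-Saharan Africa
GHA,Sub-Saharan Africa
GIN,Sub-Saharan Africa
GMB,Sub-Saharan Africa
GNB,Sub-Saharan Africa
KEN,Sub-Saharan Africa
LBR,Sub-Saharan Africa
LSO,Sub-Saharan Africa
MDG,Sub-Saharan Africa
MLI,Sub-Saharan Africa
MOZ,Sub-Saharan Africa
MRT,Sub-Saharan Africa
MUS,Sub-Saharan Africa
MWI,Sub-Saharan Africa
NAM,Sub-Saharan Africa
NER,Sub-Saharan Africa
NGA,Sub-Saharan Africa
RWA,Sub-Saharan Africa
SDN,Sub-Saharan Africa
SEN,Sub-Saharan Africa
SLE,Sub-Saharan Africa
SOM,Sub-Saharan Africa
SSD,Sub-Saharan Africa
SWZ,Sub-Saharan Africa
TCD,Sub-Saharan Africa
TGO,Sub-Saharan Africa
TZA,Sub-Saharan Africa
UGA,Sub-Saharan Africa
ZAF,Sub-Saharan Africa
ZMB,Sub-Saharan Africa
ZWE,Sub-Saharan Africa
ARE,Western Asia and Northern Africa
ARM,Western Asia and Northern Africa
AZE,Western Asia and Northern Africa
BHR,Western Asia and Northern Africa
CYP,Western Asia and Northern Africa
DZA,Western Asia and Northern Africa
EGY,Western Asia and Northern Africa
GEO,Western Asia and Northern Africa
IRQ,Western Asia and Northern Africa
ISR,Western Asia and Northern Africa
JOR,Western Asia and Northern Africa
KWT,Western Asia and Northern Africa
LBN,Western Asia and Northern Africa
LBY,Western Asia and Northern Africa
MAR,Western Asia and Northern Africa
OMN,Western Asia and Northern Africa
PSE,Western Asia and Northern Africa
QAT,Western Asia and Northern Africa
SAU,Western Asia and Northern Africa
SYR,Western Asia and Northern Africa
TUN,Western Asia and Northern Africa
TUR,Western Asia and Northern Africa
YEM,Western Asia and Northern Africa
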