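country,region
AD,europe
AE,asia
AF,asia
AG,north_america
AI,north_america
AL,europe
AM,asia
AO,africa
AR,south_america
AT,europe
AU,oceania
AW,north_america
AZ,asia
BA,europe
BB,north_america
BD,asia
BE,europe
BF,africa
BG,europe
BH,asia
BI,africa
BJ,africa
BM,north_america
BN,asia
BO,south_america
BR,south_america
BS,north_america
BT,asia
BW,africa
BY,europe
BZ,north_america
CA,north_america
CD,africa
CF,africa
CG,africa
CH,europe
CI,africa
CL,south_america
CM,africa
CN,asia
CO,south_america
CR,north_america
CU,north_america
CV,africa
CY,europe
CZ,europe
DE,europe
DJ,africa
DK,europe
DM,north_america
DO,north_america
DZ,africa
EC,south_america
EE,europe
EG,africa
ER,africa
ES,europe
ET,africa
FI,europe
FJ,oceania
FM,oceania
FR,europe
GA,africa
GB,europe
GD,north_america
GE,asia
GH,africa
GI,europe
GM,africa
GN,africa
GQ,africa
GR,europe
GT,north_america
GW,africa
GY,south_america
HK,asia
HN,north_america
HR,europe
HT,north_america
HU,europe
ID,asia
IE,europe
IL,asia
IN,asia
IQ,asia
IR,asia
IS,europe
IT,europe
JM,north_america
JO,asia
JP,asia
KE,africa
KG,asia
KH,asia
KI,oceania
KM,africa
KN,north_america
KP,asia
KR,asia
KW,asia
KY,north_america
KZ,asia
LA,asia
LB,asia
LC,north_america
LI,europe
LK,asia
LR,africa
LS,africa
LT,europe
LU,europe
LV,europe
LY,africa
MA,africa
MC,europe
MD,europe
ME,europe
MG,africa
MH,oceania
MK,europe
ML,africa
MM,asia
MN,asia
MO,asia
MR,africa
MT,europe
MU,africa
MV,asia
MW,africa
MX,north_america
MY,asia
MZ,africa
NA,africa
NE,africa
NG,africa
NI,north_america
NL,europe
NO,europe
NP,asia
NR,oceania
NZ,oceania
OM,asia
PA,north_america
PE,south_america
PG,oceania
PH,asia
PK,asia
PL,europe
PR,north_america
PS,asia
PT,europe
PW,oceania
PY,south_america
QA,asia
RO,europe
RS,europe
RU,europe
RW,africa
SA,asia
SB,oceania
SC,africa
SD,africa
SE,europe
SG,asia
SI,europe
SK,europe
SL,africa
SM,europe
SN,africa
SO,africa
SR,south_america
SS,africa
ST,africa
SV,north_america
SY,asia
SZ,africa
TD,africa
TG,africa
TH,asia
TJ,asia
TL,asia
TM,asia
TN,africa
TO,oceania
TR,asia
TT,north_america
TV,oceania
TW,asia
TZ,africa
UA,europe
UG,africa
US,north_america
UY,south_america
UZ,asia
VC,north_america
VE,south_america
VN,asia
VU,oceania
WS,oceania
YE,asia
ZA,africa
ZM,africa
ZW,africa
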