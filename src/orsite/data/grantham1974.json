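{
 "note": "Canonical published integer distances; cross-checked against AAindex GRAR740104.",
 "pairs": {
  "AC": 195,
  "AD": 126,
  "AE": 107,
  "AF": 113,
  "AG": 60,
  "AH": 86,
  "AI": 94,
  "AK": 106,
  "AL": 96,
  "AM": 84,
  "AN": 111,
  "AP": 27,
  "AQ": 91,
  "AR": 112,
  "AS": 99,
  "AT": 58,
  "AV": 64,
  "AW": 148,
  "AY": 112,
  "CD": 154,
  "CE": 170,
  "CF": 205,
  "CG": 159,
  "CH": 174,
  "CI": 198,
  "CK": 202,
  "CL": 198,
  "CM": 196,
  "CN": 139,
  "CP": 169,
  "CQ": 154,
  "CR": 180,
  "CS": 112,
  "CT": 149,
  "CV": 192,
  "CW": 215,
  "CY": 194,
  "DE": 45,
  "DF": 177,
  "DG": 94,
  "DH": 81,
  "DI": 168,
  "DK": 101,
  "DL": 172,
  "DM": 160,
  "DN": 23,
  "DP": 108,
  "DQ": 61,
  "DR": 96,
  "DS": 65,
  "DT": 85,
  "DV": 152,
  "DW": 181,
  "DY": 160,
  "EF": 140,
  "EG": 98,
  "EH": 40,
  "EI": 134,
  "EK": 56,
  "EL": 138,
  "EM": 126,
  "EN": 42,
  "EP": 93,
  "EQ": 29,
  "ER": 54,
  "ES": 80,
  "ET": 65,
  "EV": 121,
  "EW": 152,
  "EY": 122,
  "FG": 153,
  "FH": 100,
  "FI": 21,
  "FK": 102,
  "FL": 22,
  "FM": 28,
  "FN": 158,
  "FP": 114,
  "FQ": 116,
  "FR": 97,
  "FS": 155,
  "FT": 103,
  "FV": 50,
  "FW": 40,
  "FY": 22,
  "GH": 98,
  "GI": 135,
  "GK": 127,
  "GL": 138,
  "GM": 127,
  "GN": 80,
  "GP": 42,
  "GQ": 87,
  "GR": 125,
  "GS": 56,
  "GT": 59,
  "GV": 109,
  "GW": 184,
  "GY": 147,
  "HI": 94,
  "HK": 32,
  "HL": 99,
  "HM": 87,
  "HN": 68,
  "HP": 77,
  "HQ": 24,
  "HR": 29,
  "HS": 89,
  "HT": 47,
  "HV": 84,
  "HW": 115,
  "HY": 83,
  "IK": 102,
  "IL": 5,
  "IM": 10,
  "IN": 149,
  "IP": 95,
  "IQ": 109,
  "IR": 97,
  "IS": 142,
  "IT": 89,
  "IV": 29,
  "IW": 61,
  "IY": 33,
  "KL": 107,
  "KM": 95,
  "KN": 94,
  "KP": 103,
  "KQ": 53,
  "KR": 26,
  "KS": 121,
  "KT": 78,
  "KV": 97,
  "KW": 110,
  "KY": 85,
  "LM": 15,
  "LN": 153,
  "LP": 98,
  "LQ": 113,
  "LR": 102,
  "LS": 145,
  "LT": 92,
  "LV": 32,
  "LW": 61,
  "LY": 36,
  "MN": 142,
  "MP": 87,
  "MQ": 101,
  "MR": 91,
  "MS": 135,
  "MT": 81,
  "MV": 21,
  "MW": 67,
  "MY": 36,
  "NP": 91,
  "NQ": 46,
  "NR": 86,
  "NS": 46,
  "NT": 65,
  "NV": 133,
  "NW": 174,
  "NY": 143,
  "PQ": 76,
  "PR": 103,
  "PS": 74,
  "PT": 38,
  "PV": 68,
  "PW": 147,
  "PY": 110,
  "QR": 43,
  "QS": 68,
  "QT": 42,
  "QV": 96,
  "QW": 130,
  "QY": 99,
  "RS": 110,
  "RT": 71,
  "RV": 96,
  "RW": 101,
  "RY": 77,
  "ST": 58,
  "SV": 124,
  "SW": 177,
  "SY": 144,
  "TV": 69,
  "TW": 128,
  "TY": 92,
  "VW": 88,
  "VY": 55,
  "WY": 37
 },
 "residue_order": "SRLPTAVGIFYCHQNKDEMW",
 "source": "Grantham R. (1974) Science 185:862-864, Table 2"
}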