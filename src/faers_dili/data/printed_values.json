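{
  "description": "Published FAERS statin/DILI reference statistics used by validate-printed and the acceptance checks. 'dili_cases' and 'all_ae_cases' are the per-drug DILI (a) and non-DILI (b) report counts; ROR/IC columns are the published point estimates and 95% interval bounds.",
  "totals": {"dili": 7779, "non_dili": 159333, "universe": 167112},
  "signal_table": {
    "atorvastatin": {"dili_cases": 4160, "all_ae_cases": 78562, "ror": 3.09, "ror_l": 2.99, "ror_u": 3.19, "ic": 1.56, "ic_l": 1.46, "ic_u": 1.67},
    "rosuvastatin": {"dili_cases": 1590, "all_ae_cases": 40501, "ror": 2.27, "ror_l": 2.16, "ror_u": 2.39, "ic": 1.15, "ic_l": 0.98, "ic_u": 1.32},
    "simvastatin":  {"dili_cases": 1514, "all_ae_cases": 29670, "ror": 2.96, "ror_l": 2.81, "ror_u": 3.12, "ic": 1.51, "ic_l": 1.34, "ic_u": 1.68},
    "pravastatin":  {"dili_cases": 220,  "all_ae_cases": 6142,  "ror": 2.07, "ror_l": 1.81, "ror_u": 2.37, "ic": 1.02, "ic_l": 0.57, "ic_u": 1.46},
    "fluvastatin":  {"dili_cases": 169,  "all_ae_cases": 1415,  "ror": 6.90, "ror_l": 5.89, "ror_u": 8.10, "ic": 2.65, "ic_l": 2.08, "ic_u": 3.13},
    "lovastatin":   {"dili_cases": 68,   "all_ae_cases": 1419,  "ror": 2.77, "ror_l": 2.17, "ror_u": 3.53, "ic": 1.43, "ic_l": 0.59, "ic_u": 2.19},
    "pitavastatin": {"dili_cases": 52,   "all_ae_cases": 1598,  "ror": 1.88, "ror_l": 1.43, "ror_u": 2.48, "ic": 0.89, "ic_l": -0.04, "ic_u": 1.77},
    "cerivastatin": {"dili_cases": 6,    "all_ae_cases": 26,    "ror": 13.33, "ror_l": 5.49, "ror_u": 32.49, "ic": 3.46, "ic_l": -0.54, "ic_u": 4.87}
  },
  "published_signal_positive": ["atorvastatin", "rosuvastatin", "simvastatin", "pravastatin", "fluvastatin", "lovastatin"],
  "proportions": [
    {"label": "atorvastatin share of DILI cases", "numerator": 4160, "denominator": 7779, "percent": 53.48},
    {"label": "DILI hospitalization rate", "numerator": 3108, "denominator": 7779, "percent": 39.95},
    {"label": "DILI death rate", "numerator": 679, "denominator": 7779, "percent": 8.73},
    {"label": "simvastatin DILI mortality", "numerator": 184, "denominator": 1514, "percent": 12.15},
    {"label": "DILI share aged >=65", "numerator": 3534, "denominator": 7779, "percent": 45.43}
  ],
  "onset": {"overall_median_days": 26.0, "overall_iqr_days": [7.0, 80.0]},
  "dose_trend": {"drug": "atorvastatin", "doses_mg": [10, 20, 40, 80], "first_count": 471, "last_count": 655}
}
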