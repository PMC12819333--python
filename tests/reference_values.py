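"""Published reference statistics for immune-checkpoint-inhibitor-related
bullous pemphigoid reporting in FAERS (2004Q1-2025Q1), used as fixed
validation inputs.

These are printed summary numbers from a published pharmacovigilance
analysis of that cohort: per-exposure signal-table rows, cohort counts,
onset-time counts and one pairwise-test row.  Tests recompute the derived
quantities (percentages, positivity flags, adjusted p-values) from these
counts and statistics.
"""

# exposure -> (n_cases, ror, ror_low, prr, chi2, ebgm05, ic025)
SIGNAL_TABLE = {
    "All ICIs":      (850, 18.90, 17.58, 18.86, 12425.30, 15.29, 3.9),
    "PD-1i":         (744, 22.66, 20.99, 22.61, 13542.03, 18.56, 4.2),
    "Nivolumab":     (530, 29.99, 27.43, 29.90, 13550.60, 25.11, 4.6),
    "Pembrolizumab": (180, 11.24, 9.69, 11.23, 1629.07, 9.43, 3.2),
    "Cemiplimab":    (24, 37.96, 25.40, 37.81, 856.81, 25.21, 3.4),
    "Tislelizumab":  (10, 18.72, 10.06, 18.69, 167.16, 10.03, 2.0),
    "PD-L1i":        (62, 6.55, 5.10, 6.54, 288.20, 5.05, 2.2),
    "Atezolizumab":  (40, 6.43, 4.71, 6.42, 181.95, 4.68, 2.0),
    "Durvalumab":    (19, 6.81, 4.34, 6.80, 93.80, 4.33, 1.7),
    "Avelumab":      (3, 6.05, 1.95, 6.05, 12.64, 1.95, -0.1),
    "CTLA-4i":       (44, 8.79, 6.53, 8.78, 301.33, 6.49, 2.5),
    "Ipilimumab":    (44, 8.79, 6.53, 8.78, 301.33, 6.49, 2.5),
    "Nivo+Ipi":      (63, 12.71, 9.92, 12.70, 672.19, 9.81, 3.1),
    "Ate+Ipi":       (4, 24.14, 9.05, 24.08, 88.45, 9.02, 0.8),
    "Pem+Ipi":       (2, 14.80, 3.70, 14.78, 25.69, 3.69, -0.3),
    "Dur+Tre":       (1, 2.48, 0.35, 2.48, 0.88, 0.35, -1.5),
    "Ate+Tre":       (2, 35.96, 8.97, 35.82, 67.69, 8.93, -0.2),
}

MONOTHERAPY_AGENTS = ("Nivolumab", "Pembrolizumab", "Cemiplimab",
                      "Tislelizumab", "Atezolizumab", "Durvalumab",
                      "Avelumab", "Ipilimumab")

# cohort counts (all-ICIs column): sex and published shares
SEX_COUNTS = {"male": 576, "female": 187, "unspecified": 87}
SEX_SHARES_PCT = {"male": 67.8, "female": 22.0, "unspecified": 10.2}

AGE_BAND_COUNTS = {"<18": 1, "18-60": 105, ">60": 596, "missing": 148}
AGE_OVER60_SHARE_PCT = 70.1
AGE_18_60_SHARE_PCT = 12.4

COUNTRY_COUNTS = {"JP": 250, "US": 227, "FR": 138}
COUNTRY_SHARES_PCT = {"JP": 29.4, "US": 26.7, "FR": 16.2}

REPORTER_COUNTS = {"healthcare professional": 736,
                   "non-healthcare professional": 112, "missing": 2}
REPORTER_HCP_SHARE_PCT = 86.6

# onset-time counts: of 249 valid records, 44 within the first month and
# 126 after six months
TTO_N = 249
TTO_WITHIN_30D = 44
TTO_AFTER_180D = 126
TTO_WITHIN_30D_PCT = 17.7
TTO_AFTER_180D_PCT = 50.6
TTO_VALID_FRACTION = 0.2929

# one pairwise onset-time contrast: U, raw p, Bonferroni-adjusted p (m=6)
MW_ALL_VS_CTLA4 = {"u": 2350.5, "p_raw": 0.006025, "p_adj": 0.036148}
N_COMPARISONS = 6

# all-agents Weibull onset profile (n, scale, shape with 95% CI)
WEIBULL_ALL = {"n": 249, "alpha": 264.3, "beta": 0.78,
               "beta_ci": (0.69, 0.92), "failure_type": "early"}
WEIBULL_BY_CLASS = {
    "PD-1i": (295.85, 0.83),
    "PD-L1i": (137.83, 0.69),
    "CTLA-4i": (76.24, 0.48),
}
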