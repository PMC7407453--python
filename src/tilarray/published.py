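"""Published validation bookkeeping of the ~65K Nile tilapia SNP array.

These are the printed headline numbers of the platform's validation run
(probe-set class counts over the 65,450 assayed SNPs, informative-marker
counts over the 42,460 post-QC SNPs, and the per-population sample sizes
and observed heterozygosities of the nine validation populations).  The
report layer must reproduce the printed percentages from these counts
exactly; they also serve as reference inputs for the arithmetic checks.
"""

PLATFORM_TOTAL = 65_450

#: probe-set class counts of the assayed platform
PROBESET_CLASS_COUNTS = {
    "PolyHighResolution": 54_604,
    "NoMinorHom": 2_122,
    "MonoHighRes": 374,
    "OTV": 194,
    "CallRateBelowThreshold": 3_026,
    "Other": 5_130,
}

#: SNPs retained after all validation QC filters and LD pruning
POST_QC_TOTAL = 42_460

#: informative markers (MAF > 0) in the discovery population and in the
#: least-informative domesticated non-discovery strain
INFORMATIVE_DISCOVERY = 40_930
INFORMATIVE_FAST = 30_631

#: nine validation populations: (name, samples passing QC, Ho)
VALIDATION_POPULATIONS = [
    ("GIFT-Ma", 15, 0.350),
    ("GIFT-Ba", 15, 0.347),
    ("GIFT-Ph", 15, 0.328),
    ("GET-EXCEL", 15, 0.325),
    ("BEST", 14, 0.317),
    ("FaST", 15, 0.252),
    ("Kenyan", 15, 0.209),
    ("Abbassa strain", 13, 0.239),
    ("Abbassa Wild", 8, 0.258),
]
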