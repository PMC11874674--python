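"""Published reference data for the cuckoo catfish (*Synodontis multipunctatus*) study system.

The microsatellite panel characteristics (17 species-specific Smu loci scored on
81 wild adults), the roster of wild-collected embryo clutches, and the host
screening effort are reproduced here as plain constants so that panel-level
summaries and power calculations can be recomputed without any download.
Per-locus entries: sample size n, number of alleles N_A, fragment size range
(bp), observed/expected heterozygosity and the Hardy-Weinberg exact-test
p-value as published.
"""

from __future__ import annotations

# locus, repeat motif, n, N_A, size range (bp), Ho, He, P_HWE
MARKER_PANEL: list[tuple[str, str, int, int, tuple[int, int], float, float, float]] = [
    ("Smu012", "AC",   81, 12, (202, 234), 0.73, 0.80, 0.278),
    ("Smu071", "AC",   81, 15, (132, 164), 0.82, 0.84, 0.721),
    ("Smu085", "AATG", 81,  5, (319, 335), 0.60, 0.68, 0.052),
    ("Smu228", "AC",   81, 20, (95, 139),  0.96, 0.93, 0.766),
    ("Smu375", "AC",   81,  8, (306, 330), 0.73, 0.75, 0.375),
    ("Smu456", "AG",   81, 21, (186, 224), 0.90, 0.91, 0.426),
    ("Smu006", "AG",   81,  8, (228, 252), 0.72, 0.76, 0.365),
    ("Smu136", "AC",   81, 19, (83, 129),  0.85, 0.83, 0.573),
    ("Smu198", "AC",   81,  8, (208, 228), 0.63, 0.64, 0.953),
    ("Smu280", "AGG",  81,  5, (133, 151), 0.32, 0.33, 0.834),
    ("Smu408", "AG",   81, 18, (296, 334), 0.93, 0.91, 0.470),
    ("Smu185", "AC",   81,  7, (216, 228), 0.55, 0.51, 0.621),
    ("Smu308", "AC",   81,  4, (199, 205), 0.62, 0.60, 0.559),
    ("Smu318", "AC",   81, 16, (204, 236), 0.89, 0.86, 0.181),
    ("Smu328", "ATC",  81,  4, (262, 278), 0.48, 0.49, 0.816),
    ("Smu357", "AG",   81, 22, (238, 274), 0.88, 0.89, 0.062),
    ("Smu481", "AC",   81,  7, (118, 132), 0.75, 0.77, 0.589),
]

LOCUS_NAMES: list[str] = [row[0] for row in MARKER_PANEL]
ALLELE_COUNTS: list[int] = [row[3] for row in MARKER_PANEL]
PANEL_HO: list[float] = [row[5] for row in MARKER_PANEL]
PANEL_HE: list[float] = [row[6] for row in MARKER_PANEL]

# clutch_id, collection year, host species, number of embryos
CLUTCH_ROSTER: list[tuple[str, int, str, int]] = [
    ("19.GP01", 2019, "Gnathochromis pfefferi", 4),
    ("19.SD01", 2019, "Simochromis diagramma", 3),
    ("19.GP02", 2019, "Gnathochromis pfefferi", 14),
    ("19.SD02", 2019, "Simochromis diagramma", 5),
    ("19.SH01", 2019, "Shuja horei", 3),
    ("19.SD03", 2019, "Simochromis diagramma", 3),
    ("19.SD04", 2019, "Simochromis diagramma", 5),
    ("19.SD05", 2019, "Simochromis diagramma", 8),
    ("22.SH01", 2022, "Shuja horei", 8),
    ("22.SH02", 2022, "Shuja horei", 7),
    ("22.SH03", 2022, "Shuja horei", 7),
    ("22.SH04", 2022, "Shuja horei", 5),
    ("22.SH05", 2022, "Shuja horei", 6),
]

# Host screening effort across both field seasons: mouthbrooding females checked
# and parasitised broods found (382 screened/19 clutches kept from 2019 plus
# 47/5 from 2022 as genotyped; 24 parasitised clutches of 429 females overall).
N_FEMALES_SCREENED = 429
N_PARASITISED = 24

N_ADULT_REFERENCE = 81
N_EMBRYOS_GENOTYPED = 93

# mtDNA control-region validation sample used to argue dam discriminability:
# 19 embryos (one per co-hosted clutch), 13 haplotypes, haplotype diversity 0.89.
MT_VALIDATION_N = 19
MT_VALIDATION_K = 13
MT_VALIDATION_HD = 0.89
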