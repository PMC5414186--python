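"""Reference statistics of the Nile tilapia assembly upgrade.

These are the reported summary numbers for the previous short-read
reference (Orenil1.1) and the long-read replacement (O_niloticus_UMD1):
per-linkage-group anchored sizes, polishing correction counts, annotation
category counts, repeat-family totals genome-wide and inside misassembly
breakpoint regions, and the anchoring gap bookkeeping. They serve as
worked-example inputs for the report module and as regression fixtures —
every derived figure (differences, percent changes, enrichment ratios) is
recomputed from these raw values, never stored.
"""

# Anchored size (bp, including gaps) per linkage group.
ANCHORED_LG_BP_ORENIL11 = {
    "LG1": 31_194_787, "LG2": 25_048_291, "LG3": 19_325_363, "LG4": 28_679_955,
    "LG5": 37_389_089, "LG6": 36_725_243, "LG7": 51_042_256, "LG8": 29_447_820,
    "LG9": 20_956_653, "LG10": 17_092_887, "LG11": 33_447_472, "LG12": 34_679_706,
    "LG13": 32_787_261, "LG14": 34_191_023, "LG15": 26_684_556, "LG16": 34_890_008,
    "LG17": 31_749_960, "LG18": 26_198_306, "LG19": 27_159_252, "LG20": 31_470_686,
    "LG22": 26_410_405, "LG23": 20_779_993,
}

ANCHORED_LG_BP_UMD1 = {
    "LG1": 38_372_991, "LG2": 35_256_741, "LG3": 68_550_753, "LG4": 38_038_224,
    "LG5": 34_628_617, "LG6": 44_571_662, "LG7": 62_059_223, "LG8": 30_802_437,
    "LG9": 27_519_051, "LG10": 32_426_571, "LG11": 36_466_354, "LG12": 41_232_431,
    "LG13": 32_337_344, "LG14": 39_264_731, "LG15": 36_154_882, "LG16": 43_860_769,
    "LG17": 40_919_683, "LG18": 37_007_722, "LG19": 31_245_232, "LG20": 36_767_035,
    "LG22": 37_011_614, "LG23": 44_097_196,
}

# Consensus-polishing correction counts (insertions, substitutions, deletions).
QUIVER_CORRECTIONS = (1_739_112, 88_037, 43_794)
PILON_CORRECTIONS = (1_087_107, 12_402, 2_100)

# Annotation category counts (previous assembly, new assembly).
ANNOTATION_COUNTS_OLD = {
    "genes_and_pseudogenes": 30_174,
    "protein_coding": 26_329,
    "non_coding": 3_508,
    "pseudogenes": 337,
    "mRNAs": 47_700,
    "partial_mRNAs": 3_050,
}
ANNOTATION_COUNTS_NEW = {
    "genes_and_pseudogenes": 38_412,
    "protein_coding": 29_249,
    "non_coding": 8_599,
    "pseudogenes": 564,
    "mRNAs": 58_074,
    "partial_mRNAs": 393,
}

# Conserved-gene completeness: missing core orthologs, old vs new.
MISSING_BUSCOS = (427, 139)

# Anchoring gap bookkeeping of the new assembly.
N_ANCHORING_GAPS = 424
ANCHORING_GAP_SIZE = 10_000
ANCHORED_ASSEMBLY_BP = 1_009_839_889
BROKEN_CONTIG_COUNT = (2_960, 2_989)  # before/after misassembly breaking

# Repeat-family statistics: genome-wide and inside the +/-75 kbp
# misassembly breakpoint regions. (count, total_bp, pct, mean_length)
REPEAT_GENOME = {
    ("DNA", "Sola"): (7_007, 1_536_337, 0.15, 219.3),
    ("DNA", "TcMar-Tc1"): (156_588, 46_394_192, 4.60, 296.3),
    ("LINE", "L2"): (76_937, 29_334_193, 2.91, 381.3),
}
REPEAT_BREAK_REGIONS = {
    ("DNA", "Sola"): (425, 253_045, 1.37, 373.6),
    ("DNA", "TcMar-Tc1"): (846, 354_606, 9.18, 419.2),
    ("LINE", "L2"): (539, 269_645, 6.98, 500.3),
}

# Sex-patterned variant tallies: (on-target LG, off-target, total) per
# comparison and assembly.
SEXPAT_TALLIES = {
    ("niloticus_XY", "Orenil1.1"): (11_894, 17_579, 29_473),
    ("niloticus_XY", "UMD1"): (12_225, 26_493, 38_718),
    ("aureus_ZW", "Orenil1.1"): (1_445, 79_936, 81_381),
    ("aureus_ZW", "UMD1"): (24_983, 78_423, 103_406),
}
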