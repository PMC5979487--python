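"""Published reference values for the two Eucommia ulmoides plastomes.

The package's worked examples and acceptance checks replay the published
genome-scale comparison between the newly sequenced plastome (GenBank
MF766010) and the earlier one (KU204775).  The values below are the printed
results of that comparison — genome summary numbers, divergence totals, the
per-locus marker table, the large-indel inventory and the polymorphic cpSSR
set — bundled so the desk recomputations run without network access.
"""

from __future__ import annotations

GENOME_SUMMARY = {
    "MF766010": {
        "genome_size_bp": 163_586,
        "lsc_bp": 86_764,
        "ssc_bp": 14_166,
        "ir_bp": 31_328,
        "n_genes": 136, "n_genes_unique": 115,
        "n_cds": 89, "n_cds_unique": 80,
        "n_trna": 39, "n_trna_unique": 31,
        "n_rrna": 8, "n_rrna_unique": 4,
        "gc_percent": 38.33,
        "coding_percent": 51.91,
    },
    "KU204775": {
        "genome_size_bp": 163_341,
        "lsc_bp": 86_592,
        "ssc_bp": 14_149,
        "ir_bp": 31_300,
        "n_genes": 136, "n_genes_unique": 115,
        "n_cds": 89, "n_cds_unique": 80,
        "n_trna": 39, "n_trna_unique": 31,
        "n_rrna": 8, "n_rrna_unique": 4,
        "gc_percent": 38.34,
        "coding_percent": 51.99,
    },
}

DIVERGENCE_TOTALS = {
    "n_events": 155,
    "n_snp": 75,
    "n_indel": 80,
    "n_polymorphic_loci": 71,
    "region_snp": {"LSC": 51, "SSC": 12, "IR": 12},
    "region_indel": {"LSC": 47, "SSC": 3, "IR": 30},
    "n_genic_snp": 59,
    "n_spacer_indel": 50,
    "n_cds_snp": 40,
    "n_cds_indel": 14,
    "n_cds_transition": 34,
    "n_cds_transversion": 6,
    "vc_percent_min": 0.03,
    "vc_percent_max": 1.55,
    "vc_percent_mean": 0.37,
    "n_loci_mid_band": 53,  # loci with VC% between 0.10 and 1.00
}

# marker candidates: (locus, aligned length bp, number of VCs, printed VC%)
MARKER_TABLE = [
    ("infA", 234, 3, 1.28),
    ("rps18-rpl33", 343, 4, 1.17),
    ("rps12", 369, 3, 0.81),
    ("rrn5-trnR(ACG)", 266, 2, 0.75),
    ("ycf15", 210, 1, 0.48),
    ("trnI(GAU)", 1062, 5, 0.47),
    ("petB", 651, 3, 0.46),
    ("ycf3-psaA", 1502, 6, 0.40),
    ("trnT(GGU)-atpE", 261, 1, 0.38),
    ("ndhG", 531, 2, 0.38),
    ("ycf4", 546, 2, 0.37),
    ("trnG(UCC)-psbZ", 280, 1, 0.36),
    ("rps16", 1170, 4, 0.34),
    ("trnA(UGG)", 881, 3, 0.34),
    ("ndhB-rps7", 325, 1, 0.31),
    ("psbK-trnQ(UUG)", 338, 1, 0.30),
    ("trnI(CAU)-ycf2", 357, 1, 0.28),
    ("ycf15-trnL(CAA)", 359, 1, 0.28),
    ("psbB", 1521, 4, 0.27),
    ("rpl20", 384, 1, 0.26),
]

# large (> 10 bp) indels: (size bp, start position, locus, type)
LARGE_INDELS = [
    (56, 6851, "rps16-trnT(UGU)", "insertion"),
    (27, 7006, "rps16-trnT(UGU)", "insertion"),
    (45, 7196, "rps16-trnT(UGU)", "insertion"),
    (13, 12693, "ycf3-psaA", "insertion"),
    (23, 12912, "ycf3-psaA", "insertion"),
    (111, 13312, "ycf3-psaA", "insertion"),
    (12, 13471, "ycf3-psaA", "insertion"),
    (32, 24279, "psbD-trnT(GGU)", "insertion"),
    (12, 26615, "trnD(GUC)-psbM", "insertion"),
    (11, 51194, "rps12-rpl20", "insertion"),
    (17, 52547, "rps18-rpl33", "insertion"),
    (40, 57075, "psbJ-petA", "insertion"),
    (18, 64506, "accD-trnM(CAU)", "insertion"),
    (12, 73717, "trnL(UAA) intron", "insertion"),
    (14, 127486, "ndhG-ndhI", "insertion"),
    (16, 4673, "trnK(UUU)-rps16", "deletion"),
    (44, 24700, "trnG(TTU)-trnE(UUC)", "deletion"),
    (31, 41767, "atpI-atpH", "deletion"),
    (44, 51109, "rps12-rpl20", "deletion"),
    (90, 62865, "accD-trnM(CAU)", "deletion"),
]

SSR_TOTALS = {"detected": 31, "shared": 27, "polymorphic": 8}

# polymorphic cpSSRs: (motif, length range bp, locus, region)
POLYMORPHIC_SSRS = [
    ("G", "10–11", "trnG(UCC)-psbZ", "LSC"),
    ("A", "12–15", "rpoC2", "LSC"),
    ("A", "12–13", "ycf1", "IRb"),
    ("A", "13–14", "rpl32-trnL(UAG)", "IRa"),
    ("T", "10–14", "psbJ-petA", "LSC"),
    ("T", "10–11", "trnG(GCC)-trnS(GCU)", "LSC"),
    ("T", "12–13", "ycf1", "IRa"),
    ("T", "14–15", "rpl16-rps3", "LSC"),
]
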