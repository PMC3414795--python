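"""Small published worked-example datasets used in tests and docs.

These values come from a MeJA-elicitation transcriptome study of *Taxus*
cell cultures (mock-treated control vs 16 h elicited): RPKM pairs for the
taxol-biosynthesis pathway unigenes, printed annotation-rate count pairs,
and the study's headline bookkeeping counts.  They serve as inputs for
worked examples — the package recomputes derived quantities (log2 ratios,
percentages, totals) from them at run time.
"""
from __future__ import annotations

# (RPKM in control library, RPKM in elicited library) per pathway enzyme
TAXOL_PATHWAY_RPKM: dict[str, tuple[float, float]] = {
    "TS": (1.1866, 6.592),          # taxadiene synthase
    "DBAT": (2.5128, 6.2081),       # 10-O-acetyltransferase
    "TAT": (216.7005, 1130.784),    # 5-O-acetyltransferase
    "TBT": (1.1164, 1.931),         # 2-benzoyltransferase
    "T10bH": (1.2889, 22.6354),     # taxane 10-beta hydroxylase
    "T13aH": (7.4494, 8.4546),      # taxane 13-alpha hydroxylase
    "BAPT": (2.1889, 4.5731),       # phenylpropanoyltransferase
    "DBTNBT": (2.6067, 6.7517),     # 3'-N-debenzoyltaxol N-benzoyltransferase
    "T2aH": (17.2825, 27.2296),     # taxane 2-alpha hydroxylase
    "T5aH": (2.3604, 16.2127),      # taxane 5-alpha hydroxylase
    "PAM": (0.3506, 1.1578),        # phenylalanine aminomutase
    "T7bH": (0.4963, 6.7533),       # taxane 7-beta hydroxylase
}

# enzymes reported as strongly or slightly induced (clear the two-fold cut)
# vs not distinctly induced (fail it)
PATHWAY_INDUCED = frozenset(
    {"TS", "DBAT", "TAT", "T10bH", "BAPT", "DBTNBT", "T5aH", "PAM", "T7bH"}
)
PATHWAY_NOT_INDUCED = frozenset({"TBT", "T13aH", "T2aH"})

# (numerator, denominator) pairs behind printed annotation/length-bin
# percentages; keys describe the subset
ANNOTATION_RATE_PAIRS: dict[str, tuple[int, int]] = {
    "annotated_of_all_unigenes": (25812, 46581),
    "annotated_lt_500bp": (8778, 25470),
    "annotated_500_to_1000bp": (6767, 10288),
    "annotated_ge_2000bp": (3369, 3397),
    "contigs_gt_500bp_control": (14309, 109489),
}

# up- and down-regulated DEG totals under FDR <= 0.001 and |log2 ratio| >= 1
DEG_COUNTS: tuple[int, int] = (6347, 7122)

# total clean reads per library (control, elicited)
LIBRARY_READ_TOTALS: tuple[int, int] = (29459951, 29896420)
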