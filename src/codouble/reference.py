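"""Published per-gene counts for the four preradiation gametolog pairs.

These are the reported site-pattern and contingency tallies for
DDX3X/Y, RBMX/Y, USP9X/Y and UTX/UTY (cattle, human, mouse; platypus
outgroup), kept here as regression fixtures and as inputs for
reproducing the reported test statistics.  Only printed counts are
stored — every derived quantity (totals, p-values) is recomputed by
the package.

Note: the published USP9X/Y per-pattern counts sum to an
among-lineage total of 130, while the summary table reports 113 (the
within total, 96, matches).  The per-pattern counts are kept as
printed; totals derived from them are what this package reports.
"""

from __future__ import annotations

GENES = ("DDX3", "RBM", "USP9", "UTX")

#: Per-pattern site counts, pattern string -> count, per gene.
PATTERN_COUNTS: dict[str, dict[str, int]] = {
    "DDX3": {
        "000011": 17, "001100": 3, "110000": 1, "001111": 3, "110011": 0,
        "111100": 6, "000110": 8, "001001": 2, "010010": 2, "011000": 5,
        "011011": 2, "011110": 1, "100001": 2, "100100": 2, "100111": 3,
        "101101": 1, "110110": 4, "111001": 3,
    },
    "RBM": {
        "000011": 29, "001100": 3, "110000": 0, "001111": 1, "110011": 0,
        "111100": 2, "000110": 21, "001001": 0, "010010": 1, "011000": 1,
        "011011": 0, "011110": 0, "100001": 1, "100100": 0, "100111": 0,
        "101101": 0, "110110": 0, "111001": 4,
    },
    "USP9": {
        "000011": 43, "001100": 9, "110000": 9, "001111": 12, "110011": 6,
        "111100": 17, "000110": 24, "001001": 20, "010010": 8, "011000": 16,
        "011011": 5, "011110": 1, "100001": 11, "100100": 12, "100111": 6,
        "101101": 0, "110110": 10, "111001": 17,
    },
    "UTX": {
        "000011": 23, "001100": 2, "110000": 0, "001111": 5, "110011": 0,
        "111100": 3, "000110": 11, "001001": 6, "010010": 1, "011000": 5,
        "011011": 1, "011110": 1, "100001": 2, "100100": 4, "100111": 4,
        "101101": 1, "110110": 0, "111001": 6,
    },
}

#: Reported (within, among) totals from the per-gene summary table.
REPORTED_WITHIN_AMONG: dict[str, tuple[int, int]] = {
    "DDX3": (30, 35),
    "RBM": (35, 28),
    "USP9": (96, 113),
    "UTX": (33, 42),
}

#: Reported one-sided Monte-Carlo p-values of the co-double test.
REPORTED_P: dict[str, float] = {
    "DDX3": 0.0199,
    "RBM": 0.0003,
    "USP9": 0.0002,
    "UTX": 0.0390,
}

#: Transition/transversion tables: ((within_ts, within_tv), (among_ts, among_tv)).
TSTV_TABLES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "DDX3": ((27, 3), (30, 5)),
    "RBM": ((35, 7), (28, 10)),
    "USP9": ((85, 11), (116, 14)),
    "UTX": ((28, 5), (38, 4)),
}

#: Reported simulated chi-square p-values for the ts/tv tables.
REPORTED_TSTV_P: dict[str, float] = {
    "DDX3": 0.73,
    "RBM": 0.39,
    "USP9": 1.0,
    "UTX": 0.52,
}

#: Synonymous/nonsynonymous codon tables:
#: ((within_syn, within_nonsyn), (among_syn, among_nonsyn)).
SYN_NONSYN_TABLES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "DDX3": ((1, 16), (2, 17)),
    "RBM": ((0, 1), (0, 0)),
    "USP9": ((6, 34), (9, 54)),
    "UTX": ((1, 4), (0, 4)),
}

#: Reported gap-free alignment lengths (sites).
REPORTED_ALIGNMENT_LENGTHS: dict[str, int] = {
    "DDX3": 1901,
    "RBM": 950,
    "USP9": 7490,
    "UTX": 2818,
}
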