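"""Published reference numbers used by the worked examples and regression checks.

These are the printed aggregates of the benchmark evaluation that this
toolkit's methodology re-implements: per-corpus success-level histograms of
13 kernel classifiers under document-level cross-validation (CV) and of 12
under cross-learning (CL), the difficulty-class bookkeeping derived from
them, per-kernel stratum results on the difficult/easy subclasses, the
difficulty-prediction confusion matrix, and the curated list of benchmark
pairs flagged as likely annotation errors.

They serve as *inputs* to worked examples (the toolkit recomputes the
derived quantities from them); nothing in the analysis code reads them.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "CORPORA",
    "SUCCESS_CV_TOTAL",
    "SUCCESS_CV_POS",
    "SUCCESS_CL_TOTAL",
    "SUCCESS_CL_POS",
    "CLASS_OVERLAP",
    "ND_CV_STRATUM",
    "PD_CV_STRATUM",
    "DIFFICULTY_PREDICTION_CONFUSION",
    "BENCHMARK_SIZES",
    "load_flagged_pairs",
]

#: The five benchmark corpora, in canonical order.
CORPORA = ["AIMed", "BioInfer", "HPRD50", "IEPA", "LLL"]

# Success-level histograms: index = success level (number of roster
# classifiers predicting the pair's gold label), value = pair count.
# CV roster has 13 classifiers (levels 0..13), CL has 12 (levels 0..12).
SUCCESS_CV_TOTAL = {
    "AIMed": [77, 95, 105, 121, 139, 140, 142, 176, 248, 372, 461, 619, 1002, 2137],
    "BioInfer": [58, 158, 206, 306, 349, 440, 481, 619, 785, 876, 1067, 1061, 1390, 1870],
    "HPRD50": [4, 7, 12, 18, 26, 20, 33, 35, 37, 46, 61, 49, 57, 28],
    "IEPA": [2, 13, 11, 26, 30, 43, 61, 51, 79, 99, 101, 112, 106, 83],
    "LLL": [5, 7, 27, 10, 16, 21, 26, 29, 19, 26, 31, 32, 45, 36],
}

SUCCESS_CV_POS = {
    "AIMed": [73, 89, 101, 104, 115, 91, 70, 65, 72, 69, 47, 29, 43, 32],
    "BioInfer": [44, 107, 130, 198, 203, 225, 209, 248, 256, 245, 204, 164, 183, 118],
    "HPRD50": [1, 4, 8, 7, 10, 12, 9, 15, 9, 10, 33, 19, 13, 13],
    "IEPA": [1, 5, 3, 13, 10, 19, 22, 20, 31, 32, 38, 46, 47, 48],
    "LLL": [0, 0, 0, 0, 0, 2, 1, 8, 6, 15, 19, 32, 45, 36],
}

SUCCESS_CL_TOTAL = {
    "AIMed": [41, 73, 199, 315, 489, 606, 547, 725, 721, 767, 574, 414, 363],
    "BioInfer": [319, 362, 322, 303, 321, 355, 400, 432, 586, 737, 1060, 1906, 2563],
    "HPRD50": [1, 4, 7, 23, 27, 27, 41, 43, 52, 61, 50, 52, 45],
    "IEPA": [9, 19, 33, 38, 48, 44, 51, 63, 69, 107, 110, 131, 95],
    "LLL": [3, 5, 10, 19, 25, 25, 26, 20, 34, 34, 56, 50, 23],
}

SUCCESS_CL_POS = {
    "AIMed": [0, 6, 26, 39, 71, 84, 94, 136, 132, 110, 118, 69, 115],
    "BioInfer": [319, 362, 312, 280, 260, 239, 208, 190, 146, 95, 79, 29, 15],
    "HPRD50": [0, 2, 3, 10, 15, 15, 22, 18, 17, 18, 14, 16, 13],
    "IEPA": [9, 17, 32, 36, 45, 32, 34, 32, 35, 36, 13, 6, 8],
    "LLL": [3, 4, 9, 19, 25, 20, 18, 7, 18, 19, 8, 12, 2],
}

# Published difficulty/easy set sizes per corpus and their CV/CL overlap,
# for the label-blind classes (D, E) and the gold-signed subclasses.
# Layout: class -> {"cv": [...5 corpora...], "cl": [...], "both": [...]}.
CLASS_OVERLAP = {
    "D": {
        "cv": [537, 1077, 41, 82, 39],
        "cl": [628, 1003, 35, 99, 37],
        "both": [105, 530, 8, 28, 0],
    },
    "PD": {
        "cv": [162, 281, 20, 32, 17],
        "cl": [142, 319, 15, 26, 16],
        "both": [61, 111, 2, 9, 7],
    },
    "ND": {
        "cv": [463, 610, 37, 50, 39],
        "cl": [557, 644, 32, 37, 28],
        "both": [184, 295, 12, 19, 11],
    },
    "E": {
        "cv": [2137, 1870, 85, 83, 36],
        "cl": [777, 2563, 45, 95, 73],
        "both": [464, 1017, 23, 20, 4],
    },
    "PE": {
        "cv": [104, 301, 26, 48, 36],
        "cl": [115, 364, 29, 27, 22],
        "both": [49, 147, 6, 10, 7],
    },
    "NE": {
        "cv": [2105, 1752, 59, 94, 23],
        "cl": [593, 2548, 32, 87, 21],
        "both": [440, 1014, 21, 27, 8],
    },
}

# Per-kernel results on the 521 negative-difficult pairs, CV setting:
# (kernel, positive-rate r in %, observed TN, printed e, TN/e, TN/size).
ND_CV_STRATUM = [
    ("edit", 18.1, 305, 427, 0.71, 0.59),
    ("lexical", 25.0, 203, 391, 0.52, 0.39),
    ("SST", 26.6, 186, 382, 0.49, 0.36),
    ("APG", 25.3, 185, 389, 0.48, 0.36),
    ("PT", 27.9, 185, 376, 0.49, 0.36),
    ("syntactic", 24.4, 180, 394, 0.46, 0.35),
    ("cosine", 24.9, 168, 391, 0.43, 0.32),
    ("ST", 28.0, 160, 375, 0.43, 0.30),
    ("shallow", 24.6, 136, 393, 0.35, 0.26),
    ("kBSPS", 36.6, 122, 330, 0.37, 0.23),
    ("combined", 24.8, 117, 392, 0.30, 0.22),
    ("SL", 30.4, 116, 363, 0.32, 0.22),
    ("SpT", 46.4, 88, 279, 0.32, 0.17),
]
ND_SIZE = 521

# Per-kernel results on the 190 positive-difficult pairs, CV setting:
# (kernel, r, observed TP, printed e, TP/e, TP/size).
PD_CV_STRATUM = [
    ("SpT", 46.4, 71, 88, 0.81, 0.37),
    ("PT", 27.9, 33, 53, 0.62, 0.17),
    ("kBSPS", 36.6, 22, 70, 0.31, 0.12),
    ("ST", 28.0, 19, 53, 0.36, 0.10),
    ("SST", 26.6, 16, 51, 0.31, 0.08),
    ("APG", 25.3, 15, 48, 0.31, 0.08),
    ("SL", 30.4, 15, 58, 0.26, 0.08),
    ("syntactic", 24.4, 14, 46, 0.30, 0.07),
    ("edit", 18.1, 11, 34, 0.32, 0.06),
    ("lexical", 25.0, 9, 47, 0.19, 0.05),
    ("shallow", 24.6, 7, 47, 0.15, 0.04),
    ("cosine", 24.9, 7, 47, 0.15, 0.04),
    ("combined", 24.8, 4, 47, 0.09, 0.02),
]
PD_SIZE = 190

# Difficulty-class prediction by a surface-feature decision tree:
# 3x3 confusion matrix, actual rows / predicted columns in order D, N, E.
DIFFICULTY_PREDICTION_CONFUSION = [
    [148, 543, 20],
    [178, 14090, 372],
    [14, 678, 1037],
]

#: Benchmark corpus sizes (candidate pairs) and positive-class ratios.
BENCHMARK_SIZES = {
    "AIMed": (5834, 0.171),
    "BioInfer": (9666, 0.262),
    "HPRD50": (433, 0.376),
    "IEPA": (817, 0.410),
    "LLL": (330, 0.497),
}


def load_flagged_pairs() -> list[tuple[str, bool]]:
    """The 51 curated benchmark pairs flagged as likely annotation errors.

    Returns (pair id in short form, original gold label) tuples; relabeling
    them means inverting the gold label (see
    :func:`ppidiag.evaluation.relabel_and_rescore`).
    """
    text = (
        resources.files("ppidiag.data").joinpath("flagged_pairs.tsv").read_text()
    )
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "pair_id")):
            continue
        pid, gt = line.split("\t")[:2]
        out.append((pid, gt == "T"))
    return out
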