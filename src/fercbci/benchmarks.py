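"""Published per-subject benchmark of the hybrid speller design.

Reference accuracies (%) and information transfer rates (bits/min) for
ten subjects using a 36-target, frequency-enhanced row/column hybrid
P300-SSVEP speller: an offline calibration benchmark with per-modality
and hybrid results, and an online copy/free-spelling benchmark. Every
ITR in these tables is reproduced by `evaluation.itr` from its printed
accuracy with N = 36 targets and T = 0.16 min per selection, which is
the package's regression anchor for the ITR implementation.
"""

from __future__ import annotations

import pandas as pd

BENCHMARK_N_TARGETS = 36
BENCHMARK_SELECTION_TIME_MIN = 0.16

# subject: (ACC %, ITR bits/min) per modality, offline calibration
OFFLINE_BENCHMARK = {
    "S1": {"p300": (76.51, 19.86), "ssvep": (87.12, 24.72), "hybrid": (95.33, 29.11)},
    "S2": {"p300": (75.00, 19.23), "ssvep": (95.83, 29.41), "hybrid": (98.33, 31.01)},
    "S3": {"p300": (75.00, 19.23), "ssvep": (80.42, 21.58), "hybrid": (93.89, 28.28)},
    "S4": {"p300": (74.31, 18.94), "ssvep": (87.50, 24.91), "hybrid": (98.03, 30.81)},
    "S5": {"p300": (72.92, 18.36), "ssvep": (96.67, 29.93), "hybrid": (99.31, 31.72)},
    "S6": {"p300": (75.00, 19.23), "ssvep": (87.50, 24.91), "hybrid": (95.14, 29.00)},
    "S7": {"p300": (74.31, 18.94), "ssvep": (88.75, 25.53), "hybrid": (97.50, 30.46)},
    "S8": {"p300": (79.17, 21.02), "ssvep": (89.17, 25.75), "hybrid": (96.53, 29.84)},
    "S9": {"p300": (76.37, 19.81), "ssvep": (86.25, 24.29), "hybrid": (96.80, 30.01)},
    "S10": {"p300": (74.31, 18.94), "ssvep": (92.08, 27.28), "hybrid": (97.78, 30.64)},
}

# subject: (ACC %, ITR bits/min), online copy-spelling
ONLINE_BENCHMARK = {
    "S1": (88.89, 25.61),
    "S2": (94.90, 28.86),
    "S3": (90.74, 26.56),
    "S4": (92.59, 27.56),
    "S5": (100.00, 32.31),
    "S6": (98.15, 30.89),
    "S7": (93.75, 28.20),
    "S8": (90.48, 26.43),
    "S9": (95.31, 29.10),
    "S10": (98.15, 30.89),
}


def offline_frame() -> pd.DataFrame:
    """Offline benchmark as a tidy DataFrame (subject, modality, acc, itr)."""
    rows = [
        {"subject": s, "modality": m, "acc_percent": acc, "itr_bits_per_min": itr}
        for s, mods in OFFLINE_BENCHMARK.items()
        for m, (acc, itr) in mods.items()
    ]
    return pd.DataFrame(rows)


def online_frame() -> pd.DataFrame:
    rows = [
        {"subject": s, "acc_percent": acc, "itr_bits_per_min": itr}
        for s, (acc, itr) in ONLINE_BENCHMARK.items()
    ]
    return pd.DataFrame(rows)
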