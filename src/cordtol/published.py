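"""Reference values reported by the meta-analysis the packaged tables come from.

Used only by the ``reproduce`` report to show computed-vs-published deltas;
nothing in the fitting pipeline reads these numbers.
"""

from __future__ import annotations

#: Group-A pooled fits on normalized data, (alpha_beta [Gy], bed50 [Gy]).
RAT_POOLED = {
    ("thoracolumbar", "linear"): (4.1, 119.0),
    ("thoracolumbar", "nonlinear"): (3.6, 129.0),
    ("cervical", "linear"): (2.3, 198.0),
    ("cervical", "nonlinear"): (2.6, 178.0),
}

#: Per-study linear fits on the original (unnormalized) data.
RAT_PER_STUDY_ORIGINAL = {
    "Karger": (2.3, 286.0),
    "Ang": (2.3, 238.0),
    "Van der Kogel (C)": (2.5, 167.0),
    "White": (4.8, 149.0),
    "Masuda": (5.2, 149.0),
    "Van der Kogel (L)": (4.3, 111.0),
}

#: Logistic fits, (alpha_beta [Gy], bed50 [Gy], k).
RIM_GROUPS = {
    "B": (3.9, 112.0, 12.0),
    "C": (3.7, 111.0, 10.4),
    "D": (3.9, 111.0, 10.5),
}

#: Headline conversions at the combined-group parameters (Gy).
CONVERSIONS = {
    "d50_at_2gy": 73.4,
    "d50_single_fraction": 19.0,
    "bed5": 83.9,
    "d5_at_2gy": 55.4,
    "d5_single_fraction": 16.2,
}

#: Mean single-fraction D50 of the six rat datasets (Gy).
GRAND_MEAN_SINGLE_FRACTION = 22.5
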