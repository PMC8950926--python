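"""Shared test helpers and reference data."""

import numpy as np

#: Eleven-user gait summary (per-user CAD, stride/step times and lengths,
#: walking velocity and mean handle support) used as the aggregation
#: fixture; UrS None marks a below-detection (< 1 kg) support cell.
REFERENCE_TABLE = [
    {"User": "1", "CAD": 58.41, "SdT": (1.05, 0.14), "SdL": (0.55, 0.03),
     "rSpT": (0.75, 0.18), "lSpT": (0.83, 0.26), "rSpL": (0.28, 0.01),
     "lSpL": (0.27, 0.02), "WV": 0.53, "UrS": 22.68},
    {"User": "2", "CAD": 99.01, "SdT": (0.61, 0.01), "SdL": (0.35, 0.01),
     "rSpT": (0.48, 0.02), "lSpT": (0.43, 0.01), "rSpL": (0.18, 0.00),
     "lSpL": (0.17, 0.00), "WV": 0.57, "UrS": 35.17},
    {"User": "3", "CAD": 106.62, "SdT": (1.17, 0.19), "SdL": (1.01, 0.21),
     "rSpT": (0.58, 0.19), "lSpT": (0.59, 0.07), "rSpL": (0.51, 0.21),
     "lSpL": (0.51, 0.11), "WV": 0.86, "UrS": None},
    {"User": "4", "CAD": 80.91, "SdT": (0.75, 0.20), "SdL": (0.47, 0.09),
     "rSpT": (0.53, 0.17), "lSpT": (0.61, 0.31), "rSpL": (0.19, 0.02),
     "lSpL": (0.27, 0.05), "WV": 0.62, "UrS": 24.49},
    {"User": "5", "CAD": 89.36, "SdT": (0.67, 0.13), "SdL": (0.38, 0.05),
     "rSpT": (0.55, 0.19), "lSpT": (0.46, 0.18), "rSpL": (0.22, 0.02),
     "lSpL": (0.16, 0.01), "WV": 0.56, "UrS": 8.37},
    {"User": "6", "CAD": 95.17, "SdT": (0.64, 0.19), "SdL": (0.83, 0.25),
     "rSpT": (0.52, 0.42), "lSpT": (0.44, 0.13), "rSpL": (0.46, 0.14),
     "lSpL": (0.37, 0.08), "WV": 0.72, "UrS": 5.83},
    {"User": "7", "CAD": 89.67, "SdT": (0.68, 0.26), "SdL": (0.45, 0.08),
     "rSpT": (0.53, 0.31), "lSpT": (0.48, 0.27), "rSpL": (0.27, 0.04),
     "lSpL": (0.19, 0.03), "WV": 0.66, "UrS": 6.56},
    {"User": "8", "CAD": 119.42, "SdT": (0.51, 0.03), "SdL": (0.85, 0.19),
     "rSpT": (0.39, 0.08), "lSpT": (0.38, 0.03), "rSpL": (0.44, 0.11),
     "lSpL": (0.40, 0.08), "WV": 0.96, "UrS": 11.56},
    {"User": "9", "CAD": 106.15, "SdT": (0.57, 0.02), "SdL": (0.71, 0.04),
     "rSpT": (0.44, 0.04), "lSpT": (0.42, 0.02), "rSpL": (0.39, 0.02),
     "lSpL": (0.32, 0.02), "WV": 0.91, "UrS": 17.05},
    {"User": "10", "CAD": 96.91, "SdT": (0.62, 0.03), "SdL": (0.78, 0.05),
     "rSpT": (0.46, 0.04), "lSpT": (0.46, 0.05), "rSpL": (0.40, 0.03),
     "lSpL": (0.37, 0.02), "WV": 0.75, "UrS": 23.01},
    {"User": "11", "CAD": 85.94, "SdT": (0.71, 0.20), "SdL": (0.56, 0.07),
     "rSpT": (0.47, 0.11), "lSpT": (0.61, 0.35), "rSpL": (0.23, 0.02),
     "lSpL": (0.34, 0.04), "WV": 0.79, "UrS": 12.66},
]


def phase_label_at(phases, times):
    """Label lookup on a time grid (None outside all phases).

    ``phases`` may hold SupportPhase objects or (t0, t1, label) tuples.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty(times.size, dtype=object)
    for ph in phases:
        a, b, lab = (
            (ph.t_start, ph.t_end, ph.label) if hasattr(ph, "label") else ph
        )
        out[(times >= a) & (times < b)] = lab
    return out


def match_fraction(events, gt_strikes, tol=0.15, require_side=True):
    """Fraction of ground-truth heel strikes matched by a detected event."""
    matched = 0
    for t, side in gt_strikes:
        deltas = [
            abs(e.t - t)
            for e in events
            if (not require_side) or e.side == side
        ]
        if deltas and min(deltas) <= tol:
            matched += 1
    return matched / len(gt_strikes)
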