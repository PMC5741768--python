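"""10-20 montage constants: electrode sets, planar coordinates, neighbourhoods.

The full recording montage has 18 scalp sites.  Permutation-based correction
uses a reduced 12-channel montage (temporal-arc electrodes dropped because
they lack neighbours on one side, which makes interpolation of missing data
unreliable there).
"""

from __future__ import annotations

import numpy as np

#: Full 18-electrode recording montage, in canonical (anterior-to-posterior,
#: left-to-right) order.  This order is the tie-break order used whenever a
#: "first electrode wins" rule applies.
MONTAGE18 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "P4", "T6", "O1", "O2",
]

#: Temporal-arc electrodes, excluded from the permutation family.
TEMPORAL_ARC = ["F7", "F8", "T3", "T4", "T5", "T6"]

#: 12-channel montage used for permutation correction (after imputation).
MONTAGE12 = ["Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "P4", "O1", "O2"]

#: The 10 channels typically present for every subject (MONTAGE12 minus the
#: midline sites Fz and Cz, which some older montages omit).
MONTAGE10 = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]

#: Approximate 2-D head positions (unit head radius, x = right, y = anterior).
#: Used for distance-based spatial correlation in the synthetic generator.
ELECTRODE_POS = {
    "Fp1": (-0.27, 0.85), "Fp2": (0.27, 0.85),
    "F7": (-0.73, 0.53), "F3": (-0.35, 0.45), "Fz": (0.0, 0.45),
    "F4": (0.35, 0.45), "F8": (0.73, 0.53),
    "T3": (-0.90, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T4": (0.90, 0.0),
    "T5": (-0.73, -0.53), "P3": (-0.35, -0.45), "P4": (0.35, -0.45),
    "T6": (0.73, -0.53), "O1": (-0.27, -0.85), "O2": (0.27, -0.85),
}

#: Editable neighbourhood table for missing-channel imputation.  Midline rules
#: are deliberately restricted to the homologous lateral pair: a missing Fz is
#: the mean of F3/F4 and a missing Cz the mean of C3/C4.
DEFAULT_ADJACENCY = {
    "Fp1": ["Fp2", "F3", "F7"],
    "Fp2": ["Fp1", "F4", "F8"],
    "F7": ["Fp1", "F3", "T3"],
    "F3": ["Fz", "Fp1", "C3"],
    "Fz": ["F3", "F4"],
    "F4": ["Fz", "Fp2", "C4"],
    "F8": ["Fp2", "F4", "T4"],
    "T3": ["F7", "C3", "T5"],
    "C3": ["F3", "Cz", "P3", "T3"],
    "Cz": ["C3", "C4"],
    "C4": ["F4", "Cz", "P4", "T4"],
    "T4": ["F8", "C4", "T6"],
    "T5": ["T3", "P3", "O1"],
    "P3": ["C3", "O1"],
    "P4": ["C4", "O2"],
    "T6": ["T4", "P4", "O2"],
    "O1": ["P3", "O2"],
    "O2": ["P4", "O1"],
}


def electrode_distance_matrix(electrodes: list[str]) -> np.ndarray:
    """Pairwise Euclidean distances between electrode head positions."""
    pos = np.array([ELECTRODE_POS[e] for e in electrodes])
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))
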