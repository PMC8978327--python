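"""Temporal pattern classification of four-stage expression trajectories.

Each transcript's profile over (pro-B, pre-B, immature, mature) is first
normalized to the pro-B stage, then each of the three stage transitions is
labelled ``up``, ``down`` or ``flat`` by a relative (ratio) threshold,
giving one of 27 sign words such as ``down-up-down`` or ``up-up-up``
("continuously increased").  This deterministic binning reproduces the
named trajectory classes that short time-series miners such as STEM report,
without STEM's model-profile clustering or permutation p-values.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .matrix import ExpressionMatrix

SYMBOLS = ("up", "down", "flat")

#: All 27 possible three-transition sign words, lexicographic.
ALL_PATTERNS: tuple[str, ...] = tuple(
    sorted(f"{a}-{b}-{c}" for a in SYMBOLS for b in SYMBOLS for c in SYMBOLS)
)

_FLIP = {"up": "down", "down": "up", "flat": "flat"}


def normalize_to_reference(profile, pseudocount: float = 1.0) -> np.ndarray:
    """Divide a nonnegative profile by its first (reference-stage) value.

    A shared pseudocount keeps the ratio finite when the reference value is
    zero: element i maps to (v_i + pc) / (v_0 + pc).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    v = np.asarray(profile, dtype=float)
    if (v < 0).any():
        raise ValueError("profile values must be nonnegative")
    return (v + pseudocount) / (v[0] + pseudocount)


def classify_pattern(profile, delta: float = 0.2) -> str:
    """Sign word of the three stage transitions of one profile.

    A transition is ``up`` when the fold change v[i+1]/v[i] exceeds
    1 + delta, ``down`` when it falls below 1/(1 + delta), and ``flat``
    inside that band.  Ratio thresholds make the label invariant to
    rescaling the whole profile.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    v = np.asarray(profile, dtype=float)
    if v.shape != (4,):
        raise ValueError("expected a 4-stage profile")
    if (v <= 0).any():
        raise ValueError("normalized profile values must be positive")
    word = []
    for i in range(3):
        ratio = v[i + 1] / v[i]
        if ratio > 1 + delta:
            word.append("up")
        elif ratio < 1 / (1 + delta):
            word.append("down")
        else:
            word.append("flat")
    return "-".join(word)


def flip_pattern(label: str) -> str:
    """Label of the stage-reversed trajectory: word reversed, up<->down."""
    return "-".join(_FLIP[s] for s in reversed(label.split("-")))


def classify_patterns(
    matrix: ExpressionMatrix, delta: float = 0.2, pseudocount: float = 1.0
) -> dict[str, str]:
    """Pattern label per transcript, after pro-B normalization."""
    matrix.require_four_stages()
    labels: dict[str, str] = {}
    for transcript, row in matrix.data.iterrows():
        norm = normalize_to_reference(row.to_numpy(), pseudocount)
        labels[transcript] = classify_pattern(norm, delta)
    return labels


def summarize_patterns(
    matrix: ExpressionMatrix, delta: float = 0.2, pseudocount: float = 1.0
) -> dict[str, int]:
    """Count of transcripts per pattern label; counts sum to n transcripts."""
    return dict(Counter(classify_patterns(matrix, delta, pseudocount).values()))
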