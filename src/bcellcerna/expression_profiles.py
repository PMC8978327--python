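"""Expressed calls, stage-specificity (Venn) classes and stage correlation.

A transcript is "expressed" in a stage when its normalized value clears a
threshold (default 0, i.e. any nonzero signal).  Its Venn class is the
exact subset of the four stages in which it is expressed; a transcript
expressed in exactly one stage is stage-specific.  The per-stage specific
fraction — specific-to-s over expressed-in-s — is the headline statistic
distinguishing circRNAs (highly stage-restricted) from miRNAs and mRNAs
(broadly shared) across B-cell development.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import STAGES, ExpressionMatrix

#: Venn class label for a transcript expressed nowhere.
NOT_EXPRESSED = "not_expressed"

#: The 15 non-empty stage subsets plus NOT_EXPRESSED, in a fixed order.
VENN_CLASSES: tuple[str, ...] = tuple(
    "+".join(sub)
    for k in range(1, 5)
    for sub in combinations(STAGES, k)
) + (NOT_EXPRESSED,)


@dataclass(frozen=True)
class SpecificityCall:
    transcript: str
    expressed_stages: tuple[str, ...]
    venn_class: str
    is_stage_specific: bool


def call_expressed(matrix: ExpressionMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Boolean transcripts x stages table of expressed calls.

    With a positive threshold a value is expressed when value >= threshold
    (boundary inclusive); at the default threshold of 0 the rule is
    value > 0, so an all-zero transcript is never called expressed.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if threshold == 0:
        return matrix.data > 0
    return matrix.data >= threshold


def classify_specificity(expressed: pd.DataFrame) -> list[SpecificityCall]:
    """Assign each transcript its exact expressed-stage subset (Venn class)."""
    if tuple(expressed.columns) != STAGES:
        raise ValueError(f"expected stage columns {STAGES}, got {tuple(expressed.columns)}")
    calls = []
    flags = expressed.to_numpy(dtype=bool)
    for i, transcript in enumerate(expressed.index):
        stages = tuple(s for s, f in zip(STAGES, flags[i]) if f)
        venn = "+".join(stages) if stages else NOT_EXPRESSED
        calls.append(SpecificityCall(transcript, stages, venn, len(stages) == 1))
    return calls


def venn_counts(calls: list[SpecificityCall]) -> dict[str, int]:
    """Transcript count per Venn class (all 16 classes, zeros included)."""
    counts = {c: 0 for c in VENN_CLASSES}
    for call in calls:
        counts[call.venn_class] += 1
    return counts


def specificity_fraction(calls: list[SpecificityCall], stage: str) -> float | None:
    """Specific-to-stage over expressed-in-stage; None when none expressed."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    expressed = [c for c in calls if stage in c.expressed_stages]
    if not expressed:
        return None
    specific = sum(1 for c in expressed if c.is_stage_specific)
    return specific / len(expressed)


def stage_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between stage columns over all transcripts.

    Computed on the normalized values as given (no log transform).  Entries
    involving a zero-variance stage are NaN, flagged rather than silently
    zeroed; the diagonal is 1 wherever defined.
    """
    if matrix.n_transcripts < 2:
        raise ValueError("stage correlation needs at least 2 transcripts")
    values = matrix.data.to_numpy(dtype=float)
    stds = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[stds == 0, :] = np.nan
    corr[:, stds == 0] = np.nan
    return pd.DataFrame(corr, index=matrix.stages, columns=matrix.stages)
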