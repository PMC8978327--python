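"""Adjacent-stage differential expression for pooled (replicate-free) counts.

The design pools cells from three mice into one library per stage, so no
within-stage replication exists and dispersion cannot be estimated.  DE
between two stages is therefore tested per transcript with the
Audic-Claverie conditional test: given count x in a library of size N1, the
count y in a library of size N2 has, under equal underlying rates, the
conditional distribution

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1),

a negative binomial with r = x + 1 and success probability N1/(N1+N2).
The two-sided p-value doubles the smaller inclusive tail at the observed
count, capped at 1.  Because tail doubling on a discrete distribution
depends on which sample is conditioned on, the pair is first put in a
canonical orientation (lower normalized rate first), which makes the
p-value symmetric under swapping the two samples.

A transcript is called DE when p < alpha (default 0.05, no multiplicity
correction) and |log2 fold change| >= 1; Benjamini-Hochberg adjusted
p-values are reported alongside for reference but do not enter the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

#: Adjacent-stage comparisons in developmental order: label -> (numerator, denominator).
COMPARISONS: dict[str, tuple[str, str]] = {
    "PreVsPro": ("pre-B", "pro-B"),
    "ImmatureVsPre": ("immature", "pre-B"),
    "MatureVsImmature": ("mature", "immature"),
}


@dataclass(frozen=True)
class DERecord:
    transcript: str
    comparison: str
    log2fc: float
    p: float
    p_adj: float
    direction: str  # "up" | "down" | "none"
    is_de: bool


def log2_fold_change(numerator: float, denominator: float, pseudocount: float = 1.0) -> float:
    """log2((numerator + pc) / (denominator + pc)) on normalized values."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if numerator < 0 or denominator < 0:
        raise ValueError("expression values must be nonnegative")
    return float(np.log2((numerator + pseudocount) / (denominator + pseudocount)))


def _two_sided_p(x: np.ndarray, y: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Vectorized canonical-orientation Audic-Claverie two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), x.shape).copy()
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), x.shape).copy()
    # canonical orientation: condition on the sample with the lower rate
    # (ties broken by count, then library size) so the p-value is symmetric
    swap = (x / n1 > y / n2) | ((x / n1 == y / n2) & ((x > y) | ((x == y) & (n1 > n2))))
    a = np.where(swap, y, x)
    b = np.where(swap, x, y)
    na = np.where(swap, n2, n1)
    nb = np.where(swap, n1, n2)
    dist = stats.nbinom(a + 1, na / (na + nb))
    lower = dist.cdf(b)
    upper = dist.sf(b - 1)  # inclusive upper tail P(B >= b)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def count_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p for counts x, y at library sizes n1, n2.

    Symmetric under swapping (x, n1) <-> (y, n2); p = 1 when the two
    normalized rates are equal.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return float(_two_sided_p(np.array([x]), np.array([y]), n1, n2)[0])


def call_de(
    counts_num: pd.Series,
    counts_den: pd.Series,
    libsize_num: float,
    libsize_den: float,
    comparison: str = "PreVsPro",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> list[DERecord]:
    """Per-transcript DE records for one adjacent-stage comparison.

    ``counts_num``/``counts_den`` are raw counts indexed by transcript id;
    the fold change is computed on per-million normalized values with a
    pseudocount, the p-value on raw counts.  The transcript sets of the two
    series must match exactly.
    """
    if libsize_num <= 0 or libsize_den <= 0:
        raise ValueError("library sizes must be positive")
    missing = set(counts_num.index).symmetric_difference(counts_den.index)
    if missing:
        raise ValueError(f"mismatched transcript ids between stages: {sorted(missing)}")
    counts_den = counts_den.reindex(counts_num.index)

    x = counts_den.to_numpy(dtype=float)  # denominator = earlier stage
    y = counts_num.to_numpy(dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    norm_num = y / libsize_num * 1e6
    norm_den = x / libsize_den * 1e6
    lfc = np.log2((norm_num + pseudocount) / (norm_den + pseudocount))
    if len(x):
        p = _two_sided_p(x, y, libsize_den, libsize_num)
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p = p_adj = np.array([])

    records = []
    for i, transcript in enumerate(counts_num.index):
        is_de = bool(p[i] < alpha and abs(lfc[i]) >= lfc_min)
        direction = "none"
        if is_de:
            direction = "up" if lfc[i] > 0 else "down"
        records.append(DERecord(transcript, comparison, float(lfc[i]),
                                float(p[i]), float(p_adj[i]), direction, is_de))
    return records


def de_all_comparisons(
    counts: ExpressionMatrix,
    library_sizes: dict[str, float],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> dict[str, list[DERecord]]:
    """DE records for all three adjacent-stage comparisons of one layer."""
    counts.require_four_stages()
    out = {}
    for label, (num_stage, den_stage) in COMPARISONS.items():
        out[label] = call_de(
            counts.data[num_stage], counts.data[den_stage],
            library_sizes[num_stage], library_sizes[den_stage],
            comparison=label, alpha=alpha, lfc_min=lfc_min, pseudocount=pseudocount,
        )
    return out


def de_summary(records: list[DERecord]) -> dict[str, int]:
    """Counts of up- and down-regulated transcripts in one comparison."""
    return {
        "up": sum(1 for r in records if r.direction == "up"),
        "down": sum(1 for r in records if r.direction == "down"),
    }
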