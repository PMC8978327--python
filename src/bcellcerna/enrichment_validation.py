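"""Over-representation (GO/KEGG-style) enrichment and qPCR arithmetic.

Enrichment of a query gene list against annotation terms is tested with
the upper-tail hypergeometric ("at least k of n draws in the term"),
exactly the clusterProfiler convention: the background defaults to every
gene carrying at least one annotation, query genes outside the background
are dropped with a warning, and p-values are Benjamini-Hochberg corrected
across the tested terms (significant: adjusted p < 0.05).  GeneRatio is
the string "k/n": query hits in the term over annotated query size.

The qPCR side implements relative quantification by the comparative cycle
threshold (2^-ddCt) method against a reference gene (Gapdh or U6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int              # query genes in term
    n: int              # annotated query genes
    K: int              # background genes in term
    N: int              # background size
    gene_ratio: str
    p: float
    p_adj: float
    significant: bool
    genes: tuple[str, ...]


def format_gene_ratio(k: int, n: int) -> str:
    """The "k/n" GeneRatio string, e.g. (9, 70) -> "9/70"."""
    if n <= 0:
        raise ValueError("gene-ratio denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return f"{k}/{n}"


def parse_gene_ratio(ratio: str) -> tuple[int, int]:
    """Inverse of :func:`format_gene_ratio`."""
    k, n = ratio.split("/")
    return int(k), int(n)


def benjamini_hochberg(p_values) -> list[float]:
    """BH step-up adjusted p-values, order-preserving, capped at 1."""
    p = list(p_values)
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeometric_enrich(
    query: set[str],
    annotations: dict[str, set[str]],
    background: set[str] | None = None,
    term_names: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of a query set per term.

    p = sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n) with N the background size,
    K the term size, n the annotated query size and k the overlap.  Terms
    with no background gene are skipped.  Records are sorted by p
    ascending, ties by term id.
    """
    if background is None:
        background = set().union(*annotations.values()) if annotations else set()
    if not background:
        raise ValueError("empty background universe")
    dropped = query - background
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
    query_bg = query & background
    n = len(query_bg)
    N = len(background)

    records = []
    for term_id in sorted(annotations):
        term_genes = annotations[term_id] & background
        K = len(term_genes)
        if K == 0:
            continue
        hits = sorted(query_bg & term_genes)
        k = len(hits)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the inclusive tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        records.append((term_id, k, K, p, tuple(hits)))

    adjusted = benjamini_hochberg([r[3] for r in records])
    out = [
        EnrichmentRecord(
            term_id=term_id,
            term_name=(term_names or {}).get(term_id, term_id),
            k=k, n=n, K=K, N=N,
            gene_ratio=format_gene_ratio(k, n) if n > 0 else "0/0",
            p=p, p_adj=p_adj,
            significant=bool(p_adj < alpha),
            genes=hits,
        )
        for (term_id, k, K, p, hits), p_adj in zip(records, adjusted)
    ]
    return sorted(out, key=lambda r: (r.p, r.term_id))


@dataclass(frozen=True)
class DdCtInput:
    """Cycle thresholds for target and reference genes in two samples."""

    ct_target_condition: float
    ct_reference_condition: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be a positive cycle count")


def delta_delta_ct(inp: DdCtInput) -> float:
    """Fold change 2^-ddCt relative to the control sample.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt is the
    condition dCt minus the control dCt; equal dCts give fold change 1.
    """
    dct_condition = inp.ct_target_condition - inp.ct_reference_condition
    dct_control = inp.ct_target_control - inp.ct_reference_control
    return float(2.0 ** -(dct_condition - dct_control))
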