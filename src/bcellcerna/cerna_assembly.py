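"""Direction-consistent circRNA-miRNA-mRNA (ceRNA) triplet assembly.

Under the ceRNA hypothesis a circRNA sponges a miRNA away from its mRNA
target, so across a developmental transition the circRNA and the mRNA move
together and opposite to the miRNA: either decreased circRNA / increased
miRNA / decreased mRNA, or the mirror scheme.  One network is built per
transition group; a transcript belongs to a group when it is DE in exactly
that adjacent-stage comparison and in neither of the other two.  A triplet
requires the shared miRNA to carry a predicted or curated response element
on both partners (a mirna->circRNA and a mirna->mRNA interaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .differential_expression import COMPARISONS, DERecord
from .target_prediction import InteractionTable

#: Exclusive transition groups: DE in exactly this comparison.
GROUP_OF_COMPARISON: dict[str, str] = {
    "PreVsPro": "PrePro_only",
    "ImmatureVsPre": "ImmaturePre_only",
    "MatureVsImmature": "MatureImmature_only",
}
GROUPS: tuple[str, ...] = tuple(GROUP_OF_COMPARISON.values())

SCHEMES = ("circ_down_mir_up_mrna_down", "circ_up_mir_down_mrna_up")


@dataclass(frozen=True)
class ExclusiveGroup:
    transcript: str
    group: str      # one of GROUPS or "none"
    direction: str  # "up" | "down" within its group; "none" otherwise


@dataclass(frozen=True)
class CeRNATriplet:
    circ_id: str
    mirna_id: str
    mrna_id: str
    group: str
    scheme: str


def assign_exclusive_groups(records: list[DERecord]) -> list[ExclusiveGroup]:
    """Label each transcript by the single comparison it is DE in, if any.

    ``records`` must cover all three adjacent-stage comparisons for every
    transcript; a transcript DE in zero or in two-plus comparisons gets
    group "none".
    """
    by_transcript: dict[str, dict[str, DERecord]] = {}
    for rec in records:
        by_transcript.setdefault(rec.transcript, {})[rec.comparison] = rec
    out = []
    for transcript in sorted(by_transcript):
        recs = by_transcript[transcript]
        missing = set(COMPARISONS) - set(recs)
        if missing:
            raise ValueError(
                f"transcript {transcript!r} lacks DE records for {sorted(missing)}"
            )
        de_in = [label for label in COMPARISONS if recs[label].is_de]
        if len(de_in) == 1:
            label = de_in[0]
            out.append(ExclusiveGroup(transcript, GROUP_OF_COMPARISON[label],
                                      recs[label].direction))
        else:
            out.append(ExclusiveGroup(transcript, "none", "none"))
    return out


def _group_directions(groups: list[ExclusiveGroup], group_label: str) -> dict[str, str]:
    return {g.transcript: g.direction for g in groups if g.group == group_label}


def build_triplets(
    circ_groups: list[ExclusiveGroup],
    mirna_groups: list[ExclusiveGroup],
    mrna_groups: list[ExclusiveGroup],
    interactions: InteractionTable,
    group_label: str,
) -> list[CeRNATriplet]:
    """Every direction-consistent triplet of one exclusive group.

    A triplet (c, m, g) qualifies iff all three members belong to
    ``group_label``, interactions contain both m->c (circRNA kind) and
    m->g (mRNA kind), and direction(c) == direction(g) == -direction(m).
    Output is complete and sorted lexicographically.
    """
    if group_label not in GROUPS:
        raise ValueError(f"unknown group {group_label!r}; expected one of {GROUPS}")
    circ_dir = _group_directions(circ_groups, group_label)
    mirna_dir = _group_directions(mirna_groups, group_label)
    mrna_dir = _group_directions(mrna_groups, group_label)
    circ_edges = interactions.pairs("circRNA")
    mrna_edges = interactions.pairs("mRNA")

    triplets = []
    for mirna, m_dir in mirna_dir.items():
        partner_dir = "down" if m_dir == "up" else "up"
        scheme = SCHEMES[0] if m_dir == "up" else SCHEMES[1]
        circs = [c for c, d in circ_dir.items()
                 if d == partner_dir and (mirna, c) in circ_edges]
        mrnas = [g for g, d in mrna_dir.items()
                 if d == partner_dir and (mirna, g) in mrna_edges]
        for c, g in product(circs, mrnas):
            triplets.append(CeRNATriplet(c, mirna, g, group_label, scheme))
    return sorted(triplets, key=lambda t: (t.circ_id, t.mirna_id, t.mrna_id))


def network_summary(triplets: list[CeRNATriplet]) -> dict[str, int]:
    """Distinct-member and distinct-edge counts of a triplet network."""
    circ = {t.circ_id for t in triplets}
    mirna = {t.mirna_id for t in triplets}
    mrna = {t.mrna_id for t in triplets}
    sponge_edges = {(t.mirna_id, t.circ_id) for t in triplets}
    target_edges = {(t.mirna_id, t.mrna_id) for t in triplets}
    return {
        "n_circ": len(circ),
        "n_mirna": len(mirna),
        "n_mrna": len(mrna),
        "n_edges": len(sponge_edges) + len(target_edges),
    }
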