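"""End-to-end convenience: dataset in, per-group ceRNA networks out."""

from __future__ import annotations

from .cerna_assembly import GROUPS, CeRNATriplet, assign_exclusive_groups, build_triplets
from .differential_expression import de_all_comparisons
from .synthetic_data import OmicsDataset
from .target_prediction import InteractionTable, merge_interactions, predict_interactions


def predict_from_sequences(
    sequences: dict[str, str],
    mirna_prefix: str = "miR",
    circ_prefix: str = "circ",
    mrna_prefix: str = "mRNA",
    min_site_type: str = "6mer",
) -> InteractionTable:
    """Seed-match interactions from a mixed id-prefixed sequence map."""
    mirnas = {k: v for k, v in sequences.items() if k.startswith(mirna_prefix)}
    circs = {k: v for k, v in sequences.items() if k.startswith(circ_prefix)}
    mrnas = {k: v for k, v in sequences.items() if k.startswith(mrna_prefix)}
    return merge_interactions(
        predict_interactions(mirnas, circs, "circRNA", min_site_type),
        predict_interactions(mirnas, mrnas, "mRNA", min_site_type),
    )


def assemble_networks(
    dataset: OmicsDataset,
    interactions: InteractionTable | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> dict[str, list[CeRNATriplet]]:
    """DE -> exclusive groups -> direction-consistent triplets per group.

    When no interaction table is given, one is predicted by seed matching
    over the dataset's sequences.
    """
    if interactions is None:
        interactions = predict_from_sequences(dataset.sequences)
    groups = {}
    for layer in ("circ", "mirna", "mrna"):
        de = de_all_comparisons(getattr(dataset, f"{layer}_counts"),
                                dataset.library_sizes[layer],
                                alpha=alpha, lfc_min=lfc_min)
        groups[layer] = assign_exclusive_groups(
            [r for recs in de.values() for r in recs])
    return {
        g: build_triplets(groups["circ"], groups["mirna"], groups["mrna"],
                          interactions, g)
        for g in GROUPS
    }
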