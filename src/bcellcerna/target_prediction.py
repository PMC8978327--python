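"""Canonical miRNA seed-match prediction of circRNA and mRNA targets.

A miRNA represses a target through a miRNA response element (MRE): a short
stretch of the target that is Watson-Crick complementary to the miRNA seed
(miRNA nucleotides 2-7 or 2-8, counted from the 5' end).  The four canonical
site types, read 5'->3' on the target, are

========  ======================================  ======
type      target site sequence                    length
========  ======================================  ======
8mer      revcomp(miRNA[2..8]) + 'A'              8
7mer-m8   revcomp(miRNA[2..8])                    7
7mer-A1   revcomp(miRNA[2..7]) + 'A'              7
6mer      revcomp(miRNA[2..7])                    6
========  ======================================  ======

where the trailing 'A' is the adenosine opposite miRNA position 1.  This
matcher is deliberately minimal: exact canonical seeds only, no G:U wobble,
no 3'-supplementary pairing and no context scoring.  Exports from dedicated
prediction tools or interaction databases can be loaded as
:class:`InteractionTable` rows and merged with the predictions.

Coordinates are 0-based, half-open, on the target read in transcript sense;
the target itself is never reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Site types ordered strongest first; the per-start best type wins.
SITE_TYPES: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _canon(seq: str, what: str) -> str:
    """Uppercase, DNA->RNA; reject non-ACGU characters with their position."""
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in "ACGU":
            raise ValueError(f"non-ACGU character {ch!r} at position {i} in {what}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (ACGU alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """One MRE site on a target, 0-based half-open coordinates."""

    mirna_id: str
    target_id: str
    site_type: str
    start: int
    end: int


@dataclass
class Interaction:
    """An asserted miRNA -> target edge with provenance."""

    mirna_id: str
    target_id: str
    target_kind: str  # "circRNA" | "mRNA"
    sources: tuple[str, ...] = ("seed_match",)
    site_count: int = 1


@dataclass
class InteractionTable:
    """De-duplicated collection of miRNA -> target edges.

    Duplicate (mirna, target, kind) rows are merged on insertion: site
    counts are summed and source tags concatenated (order-preserving,
    unique).  A pair asserted with two different target kinds is an input
    inconsistency and raises.
    """

    rows: dict[tuple[str, str, str], Interaction] = field(default_factory=dict)

    def add(self, inter: Interaction) -> None:
        if inter.target_kind not in ("circRNA", "mRNA"):
            raise ValueError(f"unknown target_kind {inter.target_kind!r}")
        for kind in ("circRNA", "mRNA"):
            if kind != inter.target_kind and (inter.mirna_id, inter.target_id, kind) in self.rows:
                raise ValueError(
                    f"conflicting target_kind for pair "
                    f"({inter.mirna_id}, {inter.target_id}): {kind} vs {inter.target_kind}"
                )
        key = (inter.mirna_id, inter.target_id, inter.target_kind)
        if key in self.rows:
            old = self.rows[key]
            sources = old.sources + tuple(s for s in inter.sources if s not in old.sources)
            self.rows[key] = Interaction(
                inter.mirna_id, inter.target_id, inter.target_kind,
                sources, old.site_count + inter.site_count,
            )
        else:
            self.rows[key] = inter

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(sorted(self.rows.values(), key=lambda r: (r.mirna_id, r.target_id, r.target_kind)))

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self.rows

    def pairs(self, target_kind: str | None = None) -> set[tuple[str, str]]:
        """Set of (mirna, target) pairs, optionally restricted to one kind."""
        return {
            (r.mirna_id, r.target_id)
            for r in self.rows.values()
            if target_kind is None or r.target_kind == target_kind
        }


def seed_site_strings(mirna_seq: str) -> dict[str, str]:
    """The four canonical site strings a target must contain, per type."""
    m = _canon(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ValueError(f"miRNA too short for seed matching: {len(m)} < 8 nt")
    seed_2_8 = m[1:8]   # miRNA positions 2..8, 1-based
    seed_2_7 = m[1:7]   # miRNA positions 2..7
    return {
        "8mer": revcomp(seed_2_8) + "A",
        "7mer-m8": revcomp(seed_2_8),
        "7mer-A1": revcomp(seed_2_7) + "A",
        "6mer": revcomp(seed_2_7),
    }


def find_seed_matches(
    mirna_seq: str, target_seq: str, mirna_id: str = "miRNA", target_id: str = "target"
) -> list[SeedMatch]:
    """Scan a target for canonical seed sites of one miRNA.

    Every target start position is checked against the four site strings;
    when several types match at the same start (nested sites), only the
    strongest (8mer > 7mer-m8 > 7mer-A1 > 6mer) is reported.  Matches are
    returned in ascending start order.
    """
    sites = seed_site_strings(mirna_seq)
    t = _canon(target_seq, "target")
    out: list[SeedMatch] = []
    for start in range(len(t)):
        for site_type in SITE_TYPES:
            site = sites[site_type]
            if t.startswith(site, start) and start + len(site) <= len(t):
                out.append(SeedMatch(mirna_id, target_id, site_type, start, start + len(site)))
                break
    return out


def predict_interactions(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str = "mRNA",
    min_site_type: str = "6mer",
) -> InteractionTable:
    """All-vs-all seed scan; keep pairs with >=1 site of the minimum type.

    ``min_site_type`` names the weakest admissible type in the hierarchy
    8mer > 7mer-m8 > 7mer-A1 > 6mer; relaxing it never removes a pair.
    """
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}; expected one of {SITE_TYPES}")
    max_rank = _SITE_RANK[min_site_type]
    table = InteractionTable()
    for mirna_id in sorted(mirnas):
        for target_id in sorted(targets):
            matches = find_seed_matches(mirnas[mirna_id], targets[target_id], mirna_id, target_id)
            kept = [m for m in matches if _SITE_RANK[m.site_type] <= max_rank]
            if kept:
                table.add(Interaction(mirna_id, target_id, target_kind, ("seed_match",), len(kept)))
    return table


def merge_interactions(predicted: InteractionTable, loaded: InteractionTable) -> InteractionTable:
    """Union of two tables with provenance retained.

    Duplicate pairs collapse to one row (site counts summed, sources
    concatenated); the same pair with two target kinds raises.
    """
    merged = InteractionTable()
    for table in (predicted, loaded):
        for row in table:
            merged.add(Interaction(row.mirna_id, row.target_id, row.target_kind,
                                   row.sources, row.site_count))
    return merged
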