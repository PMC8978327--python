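"""Synthetic tri-omics generator with planted, recoverable ground truth.

Emulates the data regime of a four-stage bone-marrow B-cell development
experiment: one pooled library per stage (pro-B, pre-B, immature, mature)
for each of three omics layers — circRNAs (RPM), miRNAs (TPM) and mRNAs
(FPKM).  The generator plants, per layer, (i) stage-specific transcripts at
a tunable per-stage specific fraction (circRNAs are highly stage-restricted
in this system, ~60%; miRNAs/mRNAs are not), (ii) step-profile differential
expression at a given fold change in exactly one adjacent-stage comparison,
(iii) temporal sign-word patterns for circRNAs, and (iv) sponge triplets —
circRNA/miRNA/mRNA trios that are direction-consistent (circRNA and mRNA
move together, miRNA opposite) in one transition group and whose sequences
carry canonical seed sites for the shared miRNA.

Counts are Poisson (or negative-binomial) draws around the planted means;
"hard planting" writes the means straight into the normalized matrices and
rounds them into the count matrices, so exact-recovery tests are
deterministic.  Every planted fact is recorded in a :class:`GroundTruth`
object that downstream stages are tested against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import STAGES, ExpressionMatrix
from .differential_expression import COMPARISONS
from .cerna_assembly import GROUP_OF_COMPARISON, SCHEMES
from .target_prediction import find_seed_matches, revcomp, seed_site_strings

_LAYERS = ("circ", "mirna", "mrna")

#: Default planted trajectory sign words: the six characteristic circRNA
#: patterns across the three stage transitions (monotone rises and falls,
#: the two zigzags, a dip-and-plateau and a peak-then-decline).
DEFAULT_PATTERN_LABELS: tuple[str, ...] = (
    "up-up-up", "down-down-down", "down-up-down",
    "up-down-up", "down-up-flat", "up-down-down",
)


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its bounds."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study regime.

    ``frac_stage_specific_*`` is the per-stage specific fraction: among
    transcripts expressed in a stage, the fraction expressed in that stage
    only.  ``n_planted_triplets`` counts sponge triplets per transition
    group; ``n_planted_de`` extra step-profile DE transcripts per layer and
    comparison; ``n_planted_patterns`` circRNAs per trajectory label.
    """

    n_circ: int = 1005
    n_mirna: int = 1600
    n_mrna: int = 9758
    frac_stage_specific_circ: float = 0.6
    frac_stage_specific_mirna: float = 0.08
    frac_stage_specific_mrna: float = 0.08
    n_planted_patterns: int = 5
    pattern_labels: tuple[str, ...] = DEFAULT_PATTERN_LABELS
    pattern_step: float = 2.0
    n_planted_triplets: int = 5
    n_planted_de: int = 10
    de_fold_change: float = 4.0
    sequencing_depth: float = 1e6
    replicates_per_stage: int = 1
    noise_model: str = "poisson"          # "poisson" | "negative_binomial"
    dispersion: float = 0.1               # NB: var = mu + dispersion * mu^2
    baseline_mean: float = 100.0          # normalized units
    base_sigma: float = 1.0               # log-normal spread of base expression
    target_length: int = 200              # nt, planted circRNA/3'UTR sequences
    mirna_length: int = 21                # nt
    hard_planting: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_mirna", "n_mrna", "n_planted_patterns",
                     "n_planted_triplets", "n_planted_de"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("frac_stage_specific_circ", "frac_stage_specific_mirna",
                     "frac_stage_specific_mrna"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("de_fold_change", "sequencing_depth", "baseline_mean",
                     "pattern_step", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.replicates_per_stage < 1:
            raise ConfigurationError("replicates_per_stage must be >= 1")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        smallest = min(self.n_circ, self.n_mirna, self.n_mrna)
        if 3 * self.n_planted_triplets > smallest:
            raise ConfigurationError(
                f"n_planted_triplets={self.n_planted_triplets} over 3 groups needs "
                f"{3 * self.n_planted_triplets} ids per layer, but the smallest "
                f"layer has {smallest}"
            )
        for label in self.pattern_labels:
            parts = label.split("-")
            if len(parts) != 3 or any(s not in ("up", "down", "flat") for s in parts):
                raise ConfigurationError(f"malformed pattern label {label!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream testing.

    ``de_truth`` records planted effects only; a pair absent from it means
    "no planted effect" (note stage-specific transcripts do change between
    stages by construction — background nulls are listed per layer in
    ``background_ids``).
    """

    specificity_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pattern_labels: dict[str, str] = field(default_factory=dict)
    de_truth: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_triplets: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    planted_sites: dict[tuple[str, str], list[tuple[int, int, str]]] = field(default_factory=dict)
    background_ids: dict[str, list[str]] = field(default_factory=dict)

    def de_direction(self, transcript: str, comparison: str) -> str:
        return self.de_truth.get((transcript, comparison), "null")

    def validate(self) -> None:
        """Check the planted-triplet consistency invariants."""
        for circ, mirna, mrna, group, scheme in self.planted_triplets:
            comparison = next(c for c, g in GROUP_OF_COMPARISON.items() if g == group)
            dirs = (self.de_direction(circ, comparison),
                    self.de_direction(mirna, comparison),
                    self.de_direction(mrna, comparison))
            expected = ("down", "up", "down") if scheme == SCHEMES[0] else ("up", "down", "up")
            if dirs != expected:
                raise AssertionError(
                    f"triplet ({circ},{mirna},{mrna}) directions {dirs} != {expected}"
                )
            for other in set(COMPARISONS) - {comparison}:
                for member in (circ, mirna, mrna):
                    if self.de_direction(member, other) != "null":
                        raise AssertionError(
                            f"triplet member {member} planted DE outside its group"
                        )
            for target in (circ, mrna):
                if not self.planted_sites.get((mirna, target)):
                    raise AssertionError(f"no planted site for ({mirna}, {target})")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "specificity_labels": {k: list(v) for k, v in self.specificity_labels.items()},
            "pattern_labels": self.pattern_labels,
            "de_truth": [[t, c, d] for (t, c), d in sorted(self.de_truth.items())],
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "planted_sites": [
                [m, t, [list(s) for s in sites]]
                for (m, t), sites in sorted(self.planted_sites.items())
            ],
            "background_ids": self.background_ids,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(
            specificity_labels={k: tuple(v) for k, v in doc["specificity_labels"].items()},
            pattern_labels=doc["pattern_labels"],
            de_truth={(t, c): d for t, c, d in doc["de_truth"]},
            planted_triplets=[tuple(t) for t in doc["planted_triplets"]],
            planted_sites={(m, t): [tuple(s) for s in sites]
                           for m, t, sites in doc["planted_sites"]},
            background_ids=doc["background_ids"],
        )


@dataclass
class OmicsDataset:
    """The three normalized matrices, raw counts, library sizes, sequences."""

    circ_matrix: ExpressionMatrix
    mirna_matrix: ExpressionMatrix
    mrna_matrix: ExpressionMatrix
    circ_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    mrna_counts: ExpressionMatrix
    library_sizes: dict[str, dict[str, float]]   # layer -> stage -> size
    sequences: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> None:
        from . import io_formats
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for layer in _LAYERS:
            io_formats.write_expression_tsv(
                getattr(self, f"{layer}_matrix"), outdir / f"{layer}_expression.tsv")
            io_formats.write_expression_tsv(
                getattr(self, f"{layer}_counts"), outdir / f"{layer}_counts.tsv")
        libs = pd.DataFrame(self.library_sizes).T
        libs.index.name = "layer"
        libs.to_csv(outdir / "library_sizes.tsv", sep="\t", float_format="%.10g")
        if self.sequences:
            io_formats.write_fasta(self.sequences, outdir / "sequences.fa")


# -- sequence planting ------------------------------------------------------

_RNA = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA, size=length))


def _has_any_site(mirna_seq: str, target_seq: str) -> bool:
    return bool(find_seed_matches(mirna_seq, target_seq))


def generate_sequences(
    mirna_ids: list[str],
    target_ids: list[str],
    planted_interactions: list[tuple[str, str]],
    rng_seed: int,
    mirna_seqs: dict[str, str] | None = None,
    target_length: int = 200,
    mirna_length: int = 21,
    max_attempts: int = 1000,
) -> tuple[dict[str, str], dict[tuple[str, str], list[tuple[int, int, str]]]]:
    """Random sequences in which only the planted pairs have seed sites.

    Each planted (miRNA, target) pair gets one exact 8mer site written into
    the target at a recorded 0-based half-open position; target backgrounds
    are rejection-sampled until no non-planted pair has a 6mer-or-better
    site anywhere.  miRNA seeds are resampled to be pairwise distinct.
    Returns (sequences, planted_sites).
    """
    rng = np.random.default_rng(rng_seed)
    known = set(mirna_ids) | set(target_ids)
    for mirna, target in planted_interactions:
        if mirna not in known or target not in known:
            raise ValueError(f"planted interaction ({mirna}, {target}) names unknown ids")

    sequences: dict[str, str] = {}
    accepted_sites: list[dict[str, str]] = []

    def conflicts(candidate_sites: dict[str, str]) -> bool:
        # a planted 8mer of one miRNA must never embed a 6mer of another,
        # otherwise the per-target rejection loop can never succeed
        return any(
            other["6mer"] in candidate_sites["8mer"]
            or candidate_sites["6mer"] in other["8mer"]
            for other in accepted_sites
        )

    for mirna in mirna_ids:
        if mirna_seqs is not None and mirna in mirna_seqs:
            seq = mirna_seqs[mirna]
            if not seq:
                raise ValueError(f"empty miRNA sequence for {mirna!r}")
            sites = seed_site_strings(seq)
        else:
            for _ in range(max_attempts):
                seq = _random_rna(rng, mirna_length)
                sites = seed_site_strings(seq)
                if not conflicts(sites):
                    break
            else:
                raise RuntimeError(f"could not draw a distinct seed for {mirna!r}")
        accepted_sites.append(sites)
        sequences[mirna] = seq

    planted_by_target: dict[str, list[str]] = {t: [] for t in target_ids}
    for mirna, target in planted_interactions:
        planted_by_target[target].append(mirna)

    planted_sites: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for target in target_ids:
        mirnas_here = planted_by_target[target]
        if 8 * len(mirnas_here) > target_length:
            raise ValueError(f"target {target!r} too short for {len(mirnas_here)} sites")
        for _ in range(max_attempts):
            seq = list(_random_rna(rng, target_length))
            # non-overlapping 8 nt slots, one per planted miRNA
            n_slots = target_length // 8
            slots = rng.choice(n_slots, size=len(mirnas_here), replace=False)
            sites: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
            for mirna, slot in zip(mirnas_here, slots):
                start = int(slot) * 8
                site = seed_site_strings(sequences[mirna])["8mer"]
                seq[start:start + 8] = site
                sites[(mirna, target)] = [(start, start + 8, "8mer")]
            candidate = "".join(seq)
            ok = True
            for mirna in mirnas_here:
                # the recorded site must be recovered by the matcher
                matches = find_seed_matches(sequences[mirna], candidate)
                recorded = sites[(mirna, target)][0]
                if not any((m.start, m.end, m.site_type) == recorded for m in matches):
                    ok = False
                    break
            if ok:
                for mirna in mirna_ids:
                    if mirna in mirnas_here:
                        continue
                    if _has_any_site(sequences[mirna], candidate):
                        ok = False
                        break
            if ok:
                sequences[target] = candidate
                planted_sites.update(sites)
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for target {target!r} "
                f"after {max_attempts} attempts"
            )
    return sequences, planted_sites


# -- mean-profile construction ----------------------------------------------

def _step_profile(base: float, fold: float, comparison: str, direction: str) -> np.ndarray:
    """Four-stage mean profile DE in exactly one adjacent comparison.

    Stages up to the comparison's earlier stage sit at one level, stages
    from the later stage onward at the other, so every other adjacent
    comparison sees a flat ratio.
    """
    num_stage, _ = COMPARISONS[comparison]
    cut = STAGES.index(num_stage)          # first stage of the later level
    levels = np.empty(4)
    if direction == "up":
        levels[:cut], levels[cut:] = base, base * fold
    else:
        levels[:cut], levels[cut:] = base * fold, base
    return levels


def _pattern_profile(base: float, label: str, step: float) -> np.ndarray:
    values = [base]
    for symbol in label.split("-"):
        factor = step if symbol == "up" else (1 / step if symbol == "down" else 1.0)
        values.append(values[-1] * factor)
    return np.array(values)


# -- the generator ----------------------------------------------------------

def _layer_plan(
    n: int, frac_specific: float, prefix: str, cfg: SimulationConfig,
    rng: np.random.Generator, with_patterns: bool,
) -> dict:
    """Partition a layer's ids into roles and build its mean profiles."""
    ids = [f"{prefix}_{i:05d}" for i in range(1, n + 1)]
    # per-stage specific count S solving S / (n - 3S) = frac_specific
    S = int(round(n * frac_specific / (3 * frac_specific + 1))) if n else 0
    n_specific = 4 * S
    n_triplet = 3 * cfg.n_planted_triplets
    n_de = 3 * cfg.n_planted_de
    n_pattern = len(cfg.pattern_labels) * cfg.n_planted_patterns if with_patterns else 0
    needed = n_specific + n_triplet + n_de + n_pattern
    if needed > n:
        raise ConfigurationError(
            f"layer {prefix!r}: {needed} planted transcripts "
            f"({n_specific} specific + {n_triplet} triplet + {n_de} DE + "
            f"{n_pattern} pattern) exceed n={n}"
        )
    order = list(rng.permutation(n))
    cursor = 0

    def take(k):
        nonlocal cursor
        picked = [ids[j] for j in order[cursor:cursor + k]]
        cursor += k
        return picked

    specific = {stage: take(S) for stage in STAGES}
    triplet = {comp: take(cfg.n_planted_triplets) for comp in COMPARISONS}
    de_extra = {comp: take(cfg.n_planted_de) for comp in COMPARISONS}
    patterns = {label: take(cfg.n_planted_patterns)
                for label in (cfg.pattern_labels if with_patterns else ())}
    background = [ids[j] for j in order[cursor:]]
    return {
        "ids": ids, "specific": specific, "triplet": triplet,
        "de_extra": de_extra, "patterns": patterns, "background": background,
    }


def _layer_means(
    plan: dict, cfg: SimulationConfig, rng: np.random.Generator,
    truth: GroundTruth, triplet_directions: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Mean normalized values per transcript and stage; records truth."""
    ids = plan["ids"]
    row_of = {t: i for i, t in enumerate(ids)}
    arr = np.zeros((len(ids), 4))
    mu = np.log(cfg.baseline_mean) - cfg.base_sigma ** 2 / 2

    for stage, members in plan["specific"].items():
        col = STAGES.index(stage)
        bases = rng.lognormal(mu, cfg.base_sigma, size=len(members))
        for t, b in zip(members, bases):
            arr[row_of[t], col] = b
            truth.specificity_labels[t] = (stage,)
    for comp, members in plan["de_extra"].items():
        for i, t in enumerate(members):
            direction = "up" if i % 2 == 0 else "down"
            arr[row_of[t]] = _step_profile(cfg.baseline_mean, cfg.de_fold_change,
                                           comp, direction)
            truth.de_truth[(t, comp)] = direction
            truth.specificity_labels[t] = STAGES
    for comp, members in plan["triplet"].items():
        for t in members:
            direction = triplet_directions[comp][t]
            arr[row_of[t]] = _step_profile(cfg.baseline_mean, cfg.de_fold_change,
                                           comp, direction)
            truth.de_truth[(t, comp)] = direction
            truth.specificity_labels[t] = STAGES
    for label, members in plan["patterns"].items():
        for t in members:
            arr[row_of[t]] = _pattern_profile(cfg.baseline_mean, label, cfg.pattern_step)
            truth.pattern_labels[t] = label
            truth.specificity_labels[t] = STAGES
    if plan["background"]:
        bases = rng.lognormal(mu, cfg.base_sigma, size=len(plan["background"]))
        for t, b in zip(plan["background"], bases):
            arr[row_of[t]] = b
            truth.specificity_labels[t] = STAGES
    return pd.DataFrame(arr, index=ids, columns=list(STAGES))


def _sample_counts(
    mean_counts: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.hard_planting:
        return np.round(mean_counts)
    if cfg.noise_model == "poisson":
        return rng.poisson(mean_counts).astype(float)
    shape = 1.0 / cfg.dispersion
    lam = np.where(mean_counts > 0,
                   rng.gamma(shape, np.maximum(mean_counts, 1e-300) * cfg.dispersion),
                   0.0)
    return rng.poisson(lam).astype(float)


def generate_dataset(config: SimulationConfig) -> tuple[OmicsDataset, GroundTruth]:
    """Draw one synthetic tri-omics study; returns (dataset, ground truth).

    Identical config and seed reproduce bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    truth = GroundTruth()

    # plan roles per layer (consume RNG in a fixed order for determinism)
    plans = {
        "circ": _layer_plan(cfg.n_circ, cfg.frac_stage_specific_circ, "circ",
                            cfg, rng, with_patterns=True),
        "mirna": _layer_plan(cfg.n_mirna, cfg.frac_stage_specific_mirna, "miR",
                             cfg, rng, with_patterns=False),
        "mrna": _layer_plan(cfg.n_mrna, cfg.frac_stage_specific_mrna, "mRNA",
                            cfg, rng, with_patterns=False),
    }

    # triplet membership and direction schemes: triplet i of each group
    # alternates between the two schemes
    triplet_directions = {layer: {comp: {} for comp in COMPARISONS} for layer in _LAYERS}
    for comp in COMPARISONS:
        group = GROUP_OF_COMPARISON[comp]
        for i in range(cfg.n_planted_triplets):
            circ = plans["circ"]["triplet"][comp][i]
            mirna = plans["mirna"]["triplet"][comp][i]
            mrna = plans["mrna"]["triplet"][comp][i]
            scheme = SCHEMES[i % 2]
            c_dir, m_dir, g_dir = (("down", "up", "down") if scheme == SCHEMES[0]
                                   else ("up", "down", "up"))
            triplet_directions["circ"][comp][circ] = c_dir
            triplet_directions["mirna"][comp][mirna] = m_dir
            triplet_directions["mrna"][comp][mrna] = g_dir
            truth.planted_triplets.append((circ, mirna, mrna, group, scheme))

    means = {
        layer: _layer_means(plans[layer], cfg, rng, truth, triplet_directions[layer])
        for layer in _LAYERS
    }
    for layer in _LAYERS:
        truth.background_ids[layer] = list(plans[layer]["background"])

    depth = cfg.sequencing_depth * cfg.replicates_per_stage
    library_sizes = {layer: {stage: depth for stage in STAGES} for layer in _LAYERS}

    # mRNA effective lengths for the FPKM convention:
    # FPKM = count / (library/1e6 * length/1e3)
    lengths = pd.Series(rng.uniform(500, 5000, size=cfg.n_mrna),
                        index=plans["mrna"]["ids"], name="length")

    matrices, count_mats = {}, {}
    units = {"circ": "RPM", "mirna": "TPM", "mrna": "FPKM"}
    for layer in _LAYERS:
        m = means[layer]
        if layer == "mrna":
            per_transcript = (depth / 1e6) * (lengths.to_numpy()[:, None] / 1e3)
        else:
            per_transcript = depth / 1e6
        mean_counts = m.to_numpy() * per_transcript
        counts = _sample_counts(mean_counts, cfg, rng)
        if cfg.hard_planting:
            normalized = m.copy()
        else:
            normalized = pd.DataFrame(counts / per_transcript,
                                      index=m.index, columns=m.columns)
        matrices[layer] = ExpressionMatrix(normalized, unit=units[layer],
                                           lengths=lengths if layer == "mrna" else None)
        count_mats[layer] = ExpressionMatrix(
            pd.DataFrame(counts, index=m.index, columns=m.columns), unit="counts")

    # sequences for triplet members only: miRNAs plus their circRNA and
    # mRNA partners, with planted 8mer sites and clean backgrounds
    planted_pairs = [(m, c) for c, m, g, _, _ in truth.planted_triplets] + \
                    [(m, g) for c, m, g, _, _ in truth.planted_triplets]
    mirna_ids = sorted({m for _, m, _, _, _ in truth.planted_triplets})
    target_ids = sorted({c for c, _, _, _, _ in truth.planted_triplets} |
                        {g for _, _, g, _, _ in truth.planted_triplets})
    seq_seed = int(rng.integers(0, 2 ** 31 - 1))
    if planted_pairs:
        sequences, planted_sites = generate_sequences(
            mirna_ids, target_ids, planted_pairs, seq_seed,
            target_length=cfg.target_length, mirna_length=cfg.mirna_length)
        truth.planted_sites = planted_sites
    else:
        sequences = {}

    dataset = OmicsDataset(
        circ_matrix=matrices["circ"], mirna_matrix=matrices["mirna"],
        mrna_matrix=matrices["mrna"],
        circ_counts=count_mats["circ"], mirna_counts=count_mats["mirna"],
        mrna_counts=count_mats["mrna"],
        library_sizes=library_sizes, sequences=sequences,
    )
    truth.validate()
    return dataset, truth
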