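"""Deterministic synthetic data for every stage of the toolkit.

Three generators, each a pure function of (blueprint, seed):

* alignments with a planted conserved/variable block architecture, the
  situation a conservation profile is meant to resolve;
* template sets carrying planted primer sites around known insert
  variants, the ground truth for in-silico PCR and identity grouping;
* multi-gel band tables with per-gel affine warp, migration noise and
  ladder lanes, the ground truth for normalization and re-clustering.

Defaults mirror the study design these fixtures emulate: 73 samples in
seven groups of sizes 17/15/7/20/8/5/1, three-band fingerprints, a
100-bp ladder in the first and last lane of every gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .gel import GelLane, LadderSpec, MigrationCurve
from .thermo import reverse_complement

NUCS = np.array(list("ACGT"))

#: identity-group sizes of the emulated 73-isolate screen
DEFAULT_GROUP_SIZES = (17, 15, 7, 20, 8, 5, 1)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCS, size=n))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in "ACGT" if b != base])


# ------------------------------------------------------------------ MSA


@dataclass
class Block:
    kind: str  # "conserved" | "variable"
    length: int
    substitution_prob: float

    def __post_init__(self) -> None:
        if self.kind not in ("conserved", "variable"):
            raise ValueError("block kind must be conserved or variable")
        if not 0 <= self.substitution_prob <= 1:
            raise ValueError("substitution probability must be in [0,1]")


@dataclass
class MsaBlueprint:
    """Planted conserved/variable architecture for a synthetic MSA."""

    n_sequences: int = 24
    blocks: list[Block] = field(
        default_factory=lambda: [
            Block("conserved", 21, 0.01),
            Block("variable", 160, 0.30),
            Block("conserved", 21, 0.01),
        ]
    )
    indel_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(b.length for b in self.blocks) < 60:
            raise ValueError("total alignment length must be >= 60")
        if not 0 <= self.indel_prob <= 1:
            raise ValueError("indel probability must be in [0,1]")


def simulate_msa(bp: MsaBlueprint) -> tuple[Alignment, list[dict]]:
    """Simulate an alignment from a blueprint.

    Each block descends from one ancestral segment; every sequence
    substitutes each position independently with the block's
    probability, and (optionally) deletes it to a gap with
    ``indel_prob``.  Returns the alignment and the planted truth: a list
    of ``{kind, start, end}`` with 1-based inclusive block coordinates.
    """
    rng = np.random.default_rng(bp.seed)
    ancestor = "".join(
        _random_seq(rng, b.length) for b in bp.blocks
    )
    probs = np.concatenate(
        [np.full(b.length, b.substitution_prob) for b in bp.blocks]
    )
    records = []
    for k in range(bp.n_sequences):
        seq = []
        for i, base in enumerate(ancestor):
            b = _mutate_base(rng, base) if rng.random() < probs[i] else base
            if bp.indel_prob and rng.random() < bp.indel_prob:
                b = "-"
            seq.append(b)
        records.append((f"seq{k:03d}", "".join(seq)))
    truth = []
    pos = 1
    for b in bp.blocks:
        truth.append({"kind": b.kind, "start": pos, "end": pos + b.length - 1})
        pos += b.length
    return Alignment(records), truth


# ------------------------------------------------------------- templates


def simulate_templates(
    fwd_primer: str,
    rev_primer: str,
    group_variants: list[str],
    copies: list[int],
    flank_len: int = 120,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Templates with planted primer sites around known insert variants.

    Each template is ``flank + fwd_site + insert + revcomp(rev_primer) +
    flank`` with random flanks; the truth maps template id to the index
    of its insert variant (amplicon identity group).
    """
    if len(group_variants) != len(copies):
        raise ValueError("one copy count per variant")
    rng = np.random.default_rng(seed)
    templates: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    k = 0
    for g, (variant, n) in enumerate(zip(group_variants, copies)):
        for _ in range(n):
            tid = f"isolate{k:03d}"
            seq = (
                _random_seq(rng, flank_len)
                + fwd_primer
                + variant
                + reverse_complement(rev_primer)
                + _random_seq(rng, flank_len)
            )
            templates.append((tid, seq))
            truth[tid] = g
            k += 1
    order = rng.permutation(len(templates))
    templates = [templates[i] for i in order]
    return templates, truth


def default_insert_variants(
    n_groups: int = 7,
    insert_len: int = 166,
    n_polymorphic: int = 8,
    seed: int = 0,
) -> list[str]:
    """Equal-length insert variants differing at a few planted positions,
    emulating amplicon identity groups within one marker region."""
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, insert_len)
    sites = sorted(rng.choice(insert_len, size=n_polymorphic, replace=False))
    variants = [base]
    for _ in range(n_groups - 1):
        v = list(base)
        for s in sites:
            if rng.random() < 0.6:
                v[s] = _mutate_base(rng, v[s])
        variants.append("".join(v))
    # enforce pairwise distinctness
    while len(set(variants)) < n_groups:
        i = len(set(variants))
        v = list(base)
        for s in sites:
            v[s] = _mutate_base(rng, v[s])
        variants[i] = "".join(v)
    return variants


# ------------------------------------------------------------------ gels


def reference_migration_curve() -> MigrationCurve:
    """The 'true' migration physics of the simulated reference gel:
    Gaussian in log10(size), 100-bp-ladder range."""
    return MigrationCurve(
        model="gaussian",
        params=(140.0, 1.5, 1.2, 5.0),
        r_squared=1.0,
        size_range=(100.0, 1000.0),
    )


#: band slots on the reference scale, 9 units apart (>> matching
#: tolerance), all inside the ladder-calibrated position range
_BAND_SLOTS = tuple(72.0 + 9.0 * k for k in range(7))

#: Fano-plane triples: any two fingerprints share exactly one band slot,
#: so between-group Dice similarity is 33.3 % while within-group is 100 %
_FANO_LINES = (
    (0, 1, 2), (0, 3, 4), (0, 5, 6), (1, 3, 5),
    (1, 4, 6), (2, 3, 6), (2, 4, 5),
)


def default_true_patterns(n_groups: int = 7) -> dict[str, list[float]]:
    """Three-band fingerprints on the reference scale.

    Band positions sit on a grid of slots spaced 9 units apart, and the
    slot triples form a Fano-plane design: every pair of groups shares
    exactly one slot.  Non-shared bands then always differ by at least 9
    units — beyond the default tolerance of 4 plus migration noise — so
    between-group similarity is structurally pinned at one matching band.
    """
    if not 1 <= n_groups <= len(_FANO_LINES):
        raise ValueError(f"n_groups must be in 1..{len(_FANO_LINES)}")
    return {
        f"G{g + 1}": [_BAND_SLOTS[i] for i in _FANO_LINES[g]]
        for g in range(n_groups)
    }


@dataclass
class GelBlueprint:
    """Multi-gel band-table simulation with known cluster truth."""

    true_patterns: dict[str, list[float]] = field(
        default_factory=default_true_patterns
    )
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            f"G{i + 1}": n for i, n in enumerate(DEFAULT_GROUP_SIZES)
        }
    )
    n_gels: int = 8
    warp_scale_range: tuple[float, float] = (0.92, 1.08)
    warp_shift_range: tuple[float, float] = (-3.0, 3.0)
    position_noise_sd: float = 0.8
    ladder_noise_sd: float = 0.25
    ladder: LadderSpec = field(default_factory=LadderSpec.hundred_bp)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.position_noise_sd < 0 or self.ladder_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if set(self.group_sizes) != set(self.true_patterns):
            raise ValueError("group_sizes and true_patterns keys must agree")


def simulate_gel(bp: GelBlueprint) -> tuple[list[GelLane], dict[str, str]]:
    """Simulate band tables for ``bp.n_gels`` gels.

    Samples are dealt round-robin across gels; each gel gets a ladder
    lane first and last, an affine monotone warp of the reference scale,
    and Gaussian position noise.  Returns (lanes, {sample_id: group}).
    """
    rng = np.random.default_rng(bp.seed)
    ref = reference_migration_curve()
    ladder_ref = [float(ref.distance(s)) for s in bp.ladder.fragment_sizes]

    samples: list[tuple[str, str]] = []  # (sample_id, group)
    for group in sorted(bp.group_sizes):
        for k in range(bp.group_sizes[group]):
            samples.append((f"{group}_s{k + 1:02d}", group))
    order = rng.permutation(len(samples))
    samples = [samples[i] for i in order]

    warps = [
        (
            rng.uniform(*bp.warp_scale_range),
            rng.uniform(*bp.warp_shift_range),
        )
        for _ in range(bp.n_gels)
    ]
    per_gel: list[list[tuple[str, str]]] = [[] for _ in range(bp.n_gels)]
    for i, s in enumerate(samples):
        per_gel[i % bp.n_gels].append(s)

    lanes: list[GelLane] = []
    truth: dict[str, str] = {}
    for g in range(bp.n_gels):
        gel_id = f"gel{g + 1:02d}"
        scale, shift = warps[g]
        warp = lambda p: scale * p + shift

        def ladder_lane(lane_id: str) -> GelLane:
            pos = [
                warp(p) + rng.normal(0, bp.ladder_noise_sd)
                for p in ladder_ref
            ]
            return GelLane(
                gel_id=gel_id,
                lane_id=lane_id,
                bands=sorted(pos),
                is_ladder=True,
                sample_id="ladder",
            )

        lanes.append(ladder_lane("L00"))
        for k, (sample_id, group) in enumerate(per_gel[g]):
            pos = [
                warp(p) + rng.normal(0, bp.position_noise_sd)
                for p in bp.true_patterns[group]
            ]
            lanes.append(
                GelLane(
                    gel_id=gel_id,
                    lane_id=f"L{k + 1:02d}",
                    bands=sorted(pos),
                    sample_id=sample_id,
                )
            )
            truth[sample_id] = group
        lanes.append(ladder_lane(f"L{len(per_gel[g]) + 1:02d}"))
    return lanes, truth
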