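"""Universal primer-pair search over a conservation profile.

Candidate sites are windows of the alignment where every column is both
low-entropy and high-similarity; candidate oligos are the column-majority
consensus of such a window (forward) or its reverse complement (reverse).
Pairs are screened for universality across the alignment, amplicon size
near the target, an enclosed variable core (the region the fingerprint is
meant to discriminate), and nearest-neighbor thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment
from .profile import ConservationProfile
from .thermo import (
    DEFAULT_CONDITIONS,
    ThermoConditions,
    duplex_delta_g,
    hairpin_delta_g,
    melting_temperature,
    reverse_complement,
)

PRIMER_LEN_MIN = 15
PRIMER_LEN_MAX = 30


@dataclass(frozen=True)
class Window:
    """A run of conserved alignment columns (1-based inclusive)."""

    start: int
    end: int
    mean_entropy: float
    mean_similarity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PrimerCandidate:
    """A consensus oligo anchored at an alignment window."""

    sequence: str
    msa_start: int  # 1-based inclusive
    msa_end: int
    strand: str  # "forward" | "reverse"
    tm_celsius: float
    self_dimer_dg: float
    hairpin_dg: float
    mean_entropy: float
    mean_similarity: float

    def __post_init__(self) -> None:
        if not PRIMER_LEN_MIN <= len(self.sequence) <= PRIMER_LEN_MAX:
            raise ValueError(
                f"primer length {len(self.sequence)} outside "
                f"{PRIMER_LEN_MIN}..{PRIMER_LEN_MAX}"
            )
        if self.strand not in ("forward", "reverse"):
            raise ValueError("strand must be forward or reverse")


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    heterodimer_dg: float
    expected_length_range: tuple[int, int]
    universality: float
    enclosed_max_entropy: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.forward.msa_end >= self.reverse.msa_start:
            raise ValueError("forward primer must lie 5' of the reverse primer")
        if not 0.0 <= self.universality <= 1.0:
            raise ValueError("universality must be in [0, 1]")

    @property
    def amplicon_span(self) -> tuple[int, int]:
        """Alignment columns enclosed, inclusive of both primer sites."""
        return (self.forward.msa_start, self.reverse.msa_end)


def find_conserved_windows(
    profile: ConservationProfile,
    max_entropy: float,
    min_similarity: float,
    len_range: tuple[int, int] = (PRIMER_LEN_MIN, PRIMER_LEN_MAX),
) -> list[Window]:
    """Maximal runs of columns with entropy <= ``max_entropy`` and
    similarity >= ``min_similarity``, at least ``len_range[0]`` long.

    NaN (undefined) columns never qualify.
    """
    lo, hi = len_range
    if not PRIMER_LEN_MIN <= lo <= hi <= PRIMER_LEN_MAX:
        raise ValueError(f"len_range must lie within [{PRIMER_LEN_MIN},{PRIMER_LEN_MAX}]")
    ent, sim = profile.entropy, profile.similarity
    ok = (
        ~np.isnan(ent)
        & ~np.isnan(sim)
        & (ent <= max_entropy)
        & (sim >= min_similarity)
    )
    windows: list[Window] = []
    i, n = 0, len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= lo:
                windows.append(
                    Window(
                        start=i + 1,
                        end=j,
                        mean_entropy=float(np.mean(ent[i:j])),
                        mean_similarity=float(np.mean(sim[i:j])),
                    )
                )
            i = j
        else:
            i += 1
    return windows


def consensus_sequence(aln: Alignment, start: int, end: int) -> str:
    """Column-majority consensus of 1-based columns ``start..end``.

    Gap-majority columns are dropped from the oligo; ambiguity codes are
    ignored in the vote.  Ties break alphabetically for determinism.
    """
    out = []
    for i in range(start, end + 1):
        col = aln.column(i)
        counts: dict[str, int] = {}
        for sym in col:
            if sym in "ACGT" or sym == GAP:
                counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            continue
        best = max(sorted(counts), key=lambda s: counts[s])
        if best != GAP:
            out.append(best)
    return "".join(out)


def universality(
    primer: PrimerCandidate,
    aln: Alignment,
    max_mismatch: int = 0,
    anchor_3prime: int = 3,
) -> float:
    """Fraction of alignment sequences the primer binds at its site.

    Each sequence's ungapped slice at the primer window is compared to
    the primer (site orientation); a sequence matches when total
    mismatches <= ``max_mismatch`` and the 3'-terminal ``anchor_3prime``
    bases match exactly.  Length mismatches (indels in the site) count
    as non-matching.
    """
    site = (
        primer.sequence
        if primer.strand == "forward"
        else reverse_complement(primer.sequence)
    )
    hits = 0
    for _, seq in aln.records:
        slice_ = seq[primer.msa_start - 1 : primer.msa_end].replace(GAP, "")
        if len(slice_) != len(site):
            continue
        mism = [i for i in range(len(site)) if slice_[i] != site[i]]
        if len(mism) > max_mismatch:
            continue
        if anchor_3prime > 0:
            if primer.strand == "forward":
                anchor = range(len(site) - anchor_3prime, len(site))
            else:
                anchor = range(0, anchor_3prime)
            if any(i in anchor for i in mism):
                continue
        hits += 1
    return hits / aln.n_sequences


def _candidate(
    aln: Alignment,
    profile: ConservationProfile,
    start: int,
    end: int,
    strand: str,
    cond: ThermoConditions,
) -> PrimerCandidate | None:
    consensus = consensus_sequence(aln, start, end)
    if not PRIMER_LEN_MIN <= len(consensus) <= PRIMER_LEN_MAX:
        return None
    seq = consensus if strand == "forward" else reverse_complement(consensus)
    return PrimerCandidate(
        sequence=seq,
        msa_start=start,
        msa_end=end,
        strand=strand,
        tm_celsius=melting_temperature(seq, cond),
        self_dimer_dg=duplex_delta_g(seq, seq),
        hairpin_dg=hairpin_delta_g(seq),
        mean_entropy=float(np.nanmean(profile.entropy[start - 1 : end])),
        mean_similarity=float(np.nanmean(profile.similarity[start - 1 : end])),
    )


def _ungapped_len(aln: Alignment, start: int, end: int) -> tuple[int, int]:
    """Min/max ungapped length of alignment span ``start..end`` across rows."""
    lens = [
        len(seq[start - 1 : end].replace(GAP, "")) for _, seq in aln.records
    ]
    return (min(lens), max(lens))


@dataclass
class PairConstraints:
    """Search constraints for :func:`enumerate_pairs`.

    ``amplicon_len_target`` is the ideal product size in nt; products
    must fall within ``amplicon_len_range`` across all templates.  When
    ``require_variable_core`` is set, a pair must enclose at least one
    column whose entropy exceeds the ``variable_core_quantile`` of the
    profile (the hypervariable region the assay reads out).
    """

    amplicon_len_target: int = 200
    amplicon_len_range: tuple[int, int] = (150, 260)
    primer_len_range: tuple[int, int] = (18, 24)
    require_variable_core: bool = True
    variable_core_quantile: float = 0.90
    max_mismatch: int = 0
    anchor_3prime: int = 3
    min_universality: float = 1.0
    max_self_dimer_dg: float = -15.0  # reject below (too stable)
    max_hairpin_dg: float = -6.0
    max_heterodimer_dg: float = -12.0
    thermo: ThermoConditions = field(default_factory=lambda: DEFAULT_CONDITIONS)


def enumerate_pairs(
    windows: Sequence[Window],
    profile: ConservationProfile,
    aln: Alignment,
    constraints: PairConstraints | None = None,
) -> list[PrimerPair]:
    """Enumerate and rank primer pairs from conserved windows.

    Every primer-length sub-window of each conserved window yields one
    forward and one reverse candidate; all forward x reverse combinations
    are screened against the constraints.  Ranking: universality (desc),
    enclosed max entropy (desc), |expected length - target| (asc),
    thermodynamic penalty (asc); ties break by leftmost forward start.
    """
    c = constraints or PairConstraints()
    if not windows:
        return []
    lo, hi = c.primer_len_range
    ent = profile.entropy
    threshold = float(np.nanquantile(ent, c.variable_core_quantile))

    fwd: list[PrimerCandidate] = []
    rev: list[PrimerCandidate] = []
    for w in windows:
        for length in range(lo, hi + 1):
            for s in range(w.start, w.end - length + 2):
                e = s + length - 1
                for strand, bucket in (("forward", fwd), ("reverse", rev)):
                    cand = _candidate(aln, profile, s, e, strand, c.thermo)
                    if cand is None:
                        continue
                    if cand.self_dimer_dg < c.max_self_dimer_dg:
                        continue
                    if cand.hairpin_dg < c.max_hairpin_dg:
                        continue
                    bucket.append(cand)

    pairs: list[PrimerPair] = []
    for f in fwd:
        u_f = universality(f, aln, c.max_mismatch, c.anchor_3prime)
        if u_f < c.min_universality:
            continue
        for r in rev:
            if f.msa_end >= r.msa_start:
                continue
            len_range = _ungapped_len(aln, f.msa_start, r.msa_end)
            if len_range[0] < c.amplicon_len_range[0]:
                continue
            if len_range[1] > c.amplicon_len_range[1]:
                continue
            enclosed = ent[f.msa_end : r.msa_start - 1]
            enclosed_max = (
                float(np.nanmax(enclosed)) if enclosed.size else 0.0
            )
            if c.require_variable_core and not (enclosed_max > threshold):
                continue
            u_r = universality(r, aln, c.max_mismatch, c.anchor_3prime)
            u = min(u_f, u_r)
            if u < c.min_universality:
                continue
            het = duplex_delta_g(f.sequence, r.sequence)
            if het < c.max_heterodimer_dg:
                continue
            thermo_penalty = (
                abs(f.tm_celsius - r.tm_celsius)
                + max(0.0, -f.self_dimer_dg)
                + max(0.0, -r.self_dimer_dg)
                + max(0.0, -het)
            )
            mid = (len_range[0] + len_range[1]) / 2
            pair = PrimerPair(
                forward=f,
                reverse=r,
                heterodimer_dg=het,
                expected_length_range=len_range,
                universality=u,
                enclosed_max_entropy=enclosed_max,
            )
            pair.score = (
                -u * 1000.0
                - enclosed_max * 100.0
                + abs(mid - c.amplicon_len_target)
                + 0.1 * thermo_penalty
            )
            pairs.append(pair)

    pairs.sort(key=lambda p: (p.score, p.forward.msa_start, p.reverse.msa_start))
    return pairs


def pairs_to_frame(pairs: Sequence[PrimerPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "fwd_seq": p.forward.sequence,
                "rev_seq": p.reverse.sequence,
                "fwd_start": p.forward.msa_start,
                "fwd_end": p.forward.msa_end,
                "rev_start": p.reverse.msa_start,
                "rev_end": p.reverse.msa_end,
                "fwd_tm": p.forward.tm_celsius,
                "rev_tm": p.reverse.tm_celsius,
                "fwd_self_dimer_dg": p.forward.self_dimer_dg,
                "rev_self_dimer_dg": p.reverse.self_dimer_dg,
                "fwd_hairpin_dg": p.forward.hairpin_dg,
                "rev_hairpin_dg": p.reverse.hairpin_dg,
                "heterodimer_dg": p.heterodimer_dg,
                "universality": p.universality,
                "len_min": p.expected_length_range[0],
                "len_max": p.expected_length_range[1],
                "enclosed_max_entropy": p.enclosed_max_entropy,
                "score": p.score,
            }
        )
    return pd.DataFrame(rows)


def write_pairs(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, float_format="%.4g")
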