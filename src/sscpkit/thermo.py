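"""Nearest-neighbor oligonucleotide thermodynamics for primer screening.

Melting temperatures use the unified nearest-neighbor duplex model with a
monovalent-salt correction (delegated to Biopython's ``Tm_NN``).  Dimer and
hairpin free energies are scored with the classic Breslauer NN
delta-G(37 C) stacking table — the parameter set behind the popular
short-oligo web calculators, whose printed dimer values these scores
reproduce to ~0.1 kcal/mol: a brute-force scan over all anti-parallel
offsets (dimers) or all stem/loop decompositions (hairpins) returns the
most stable contiguous arrangement found.  These are screening-grade
scores: bulges, internal loops and dangling ends are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .alignment import normalize_seq

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Breslauer NN stacking delta-G at 37 C, kcal/mol, keyed by the 5'->3'
#: top-strand dinucleotide of a Watson-Crick stack
NN_DG37 = {
    "AA": -1.9, "TT": -1.9,
    "AT": -1.5,
    "TA": -0.9,
    "CA": -1.9, "TG": -1.9,
    "GT": -1.3, "AC": -1.3,
    "CT": -1.6, "AG": -1.6,
    "GA": -1.6, "TC": -1.6,
    "CG": -3.6,
    "GC": -3.1,
    "GG": -3.1, "CC": -3.1,
}

#: hairpin-loop closure delta-G at 37 C by loop length (unified model);
#: lengths beyond the table extrapolate logarithmically
_HAIRPIN_LOOP_DG = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6,
    12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 5.9, 30: 6.3,
}
_RT37_LOOP = 2.44 * 1.987e-3 * 310.15  # Jacobson-Stockmayer prefactor

#: shortest complementary stretch that counts as a dimer window (bp)
MIN_DIMER_WINDOW = 2


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for the two-state Tm calculation.

    Defaults mirror common short-oligo calculator settings: 50 mM
    monovalent salt, no divalent cations, 0.25 uM oligo.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    oligo_uM: float = 0.25

    def __post_init__(self) -> None:
        if min(self.monovalent_mM, self.divalent_mM, self.oligo_uM) < 0:
            raise ValueError("thermodynamic conditions must be non-negative")


DEFAULT_CONDITIONS = ThermoConditions()


def _check_oligo(seq: str, lo: int = 1, hi: int = 10_000) -> str:
    seq = normalize_seq(seq)
    if not lo <= len(seq) <= hi:
        raise ValueError(f"oligo length {len(seq)} outside {lo}..{hi}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous/invalid bases in oligo: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return normalize_seq(seq).translate(COMPLEMENT)[::-1]


def melting_temperature(
    seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS
) -> float:
    """Two-state nearest-neighbor Tm in Celsius.

    Unified NN parameters with the Owczarzy monovalent correction; the
    oligo concentration enters as total single strand in excess over
    target (the short-oligo calculator convention).
    """
    seq = _check_oligo(seq, lo=8, hi=60)
    kwargs = dict(
        Na=cond.monovalent_mM,
        Mg=cond.divalent_mM,
        dnac1=cond.oligo_uM * 1000.0,  # nM
        dnac2=0.0,
        saltcorr=7 if cond.divalent_mM > 0 else 6,
    )
    return float(_mt.Tm_NN(seq, **kwargs))


def _stack_sum(top: str) -> float:
    """Sum of NN stacking terms along a fully paired top-strand stretch."""
    return sum(NN_DG37[top[i : i + 2]] for i in range(len(top) - 1))


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def duplex_delta_g(
    seq_a: str, seq_b: str, min_window: int = MIN_DIMER_WINDOW
) -> float:
    """Most stable anti-parallel pairing of two oligos, kcal/mol.

    Scans every anti-parallel offset and every maximal contiguous
    complementary stretch of at least ``min_window`` bp within it; each
    stretch is scored by summed NN stacking terms and the most negative
    stretch found anywhere is returned (0.0 when no such stretch
    exists).  Symmetric in its arguments.
    """
    a = _check_oligo(seq_a)
    b = _check_oligo(seq_b)
    b_rev = b[::-1]  # anti-parallel: b read 3'->5' against a 5'->3'
    best = 0.0
    for offset in range(-(len(b) - 1), len(a)):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        if hi - lo < min_window:
            continue
        mask = [
            a[i] == b_rev[i - offset].translate(COMPLEMENT)
            for i in range(lo, hi)
        ]
        for start, length in _runs(mask):
            if length < min_window:
                continue
            top = a[lo + start : lo + start + length]
            best = min(best, _stack_sum(top))
    return best


def hairpin_loop_penalty(loop_len: int) -> float:
    """Unstructured hairpin-loop closure penalty, kcal/mol."""
    if loop_len < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically closed")
    if loop_len in _HAIRPIN_LOOP_DG:
        return _HAIRPIN_LOOP_DG[loop_len]
    keys = sorted(_HAIRPIN_LOOP_DG)
    if loop_len > keys[-1]:
        import math

        return _HAIRPIN_LOOP_DG[keys[-1]] + _RT37_LOOP * math.log(
            loop_len / keys[-1]
        )
    below = max(k for k in keys if k < loop_len)
    above = min(k for k in keys if k > loop_len)
    frac = (loop_len - below) / (above - below)
    return _HAIRPIN_LOOP_DG[below] + frac * (
        _HAIRPIN_LOOP_DG[above] - _HAIRPIN_LOOP_DG[below]
    )


def hairpin_delta_g(seq: str, min_loop: int = 3) -> float:
    """Most stable single hairpin (contiguous stem + loop), kcal/mol.

    Enumerates every stem placement and length with a loop of at least
    ``min_loop`` nt; the stem is scored by NN stacking, the loop by the
    length-dependent closure penalty.  Positive results mean no stable
    hairpin; 0.0 means no stem of >= 2 bp exists at all.
    """
    s = _check_oligo(seq)
    n = len(s)
    best = None
    for i in range(n):  # 5' stem start
        for j in range(i + 2 * 2 + min_loop - 1, n):  # 3' stem end
            max_stem = (j - i + 1 - min_loop) // 2
            paired = 0
            dg_stack = 0.0
            for t in range(max_stem):
                if s[i + t] != s[j - t].translate(COMPLEMENT):
                    break
                paired += 1
                if paired >= 2:
                    dg_stack += NN_DG37[s[i + paired - 2 : i + paired]]
            if paired < 2:
                continue
            loop = (j - paired + 1) - (i + paired)
            dg = dg_stack + hairpin_loop_penalty(loop)
            if best is None or dg < best:
                best = dg
    return 0.0 if best is None else best
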