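"""In-silico PCR: binding-site search, amplicon extraction, grouping.

The amplicon runs from the first base of the forward primer site to the
last base of the reverse primer site (both primer regions included), so
reported lengths match what a gel would show.  Products outside the size
window are discarded — the computational analogue of cutting the expected
band out of a sizing gel.  Templates that yield no in-window product, or
more than one, get an explicit status instead of being dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment import normalize_seq
from .thermo import reverse_complement

PLUS = "+"
MINUS = "-"


@dataclass(frozen=True)
class BindingSite:
    """A primer match on a template (0-based half-open interval)."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class Amplicon:
    template_id: str
    sequence: str
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def length(self) -> int:
        return len(self.sequence)


class NoAmplification(Exception):
    """No product inside the size window for this template."""


class AmbiguousProduct(Exception):
    """More than one product inside the size window."""


def find_binding_sites(
    template: str,
    primer: str,
    max_mismatch: int = 2,
    anchor_3prime: int = 3,
) -> list[BindingSite]:
    """All plus-strand matches of ``primer`` and minus-strand matches of
    its reverse complement on ``template``.

    A position matches when total mismatches <= ``max_mismatch`` with
    zero mismatches in the 3'-terminal ``anchor_3prime`` bases (the end
    the polymerase extends).  Ambiguous template bases count as
    mismatches.
    """
    template = normalize_seq(template)
    primer = normalize_seq(primer)
    n, k = len(template), len(primer)
    if k == 0 or k > n:
        return []
    sites: list[BindingSite] = []
    rc = reverse_complement(primer)
    for strand, probe in ((PLUS, primer), (MINUS, rc)):
        # 3' anchor of a plus-strand primer is its last bases; for the
        # minus strand the primer's 3' end maps to the probe's start.
        if strand == PLUS:
            anchor = range(k - anchor_3prime, k)
        else:
            anchor = range(0, anchor_3prime)
        for i in range(n - k + 1):
            window = template[i : i + k]
            mism = [j for j in range(k) if window[j] != probe[j]]
            if len(mism) > max_mismatch:
                continue
            if anchor_3prime > 0 and any(j in anchor for j in mism):
                continue
            sites.append(BindingSite(i, i + k, strand, len(mism)))
    return sites


def enumerate_products(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 2,
    anchor_3prime: int = 3,
) -> list[tuple[BindingSite, BindingSite]]:
    """All (forward plus-strand, reverse minus-strand) site combinations
    with the forward site upstream of the reverse site."""
    fwd_sites = [
        s
        for s in find_binding_sites(template, fwd_primer, max_mismatch, anchor_3prime)
        if s.strand == PLUS
    ]
    rev_sites = [
        s
        for s in find_binding_sites(template, rev_primer, max_mismatch, anchor_3prime)
        if s.strand == MINUS
    ]
    return [
        (f, r) for f in fwd_sites for r in rev_sites if f.end <= r.start
    ]


def amplify(
    template_id: str,
    template: str,
    fwd_primer: str,
    rev_primer: str,
    size_window: tuple[int, int] = (150, 300),
    max_mismatch: int = 2,
    anchor_3prime: int = 3,
) -> Amplicon:
    """Extract the unique in-window product of a primer pair.

    Raises
    ------
    NoAmplification
        No product, or none inside ``size_window``.
    AmbiguousProduct
        More than one in-window product.
    """
    template = normalize_seq(template)
    lo, hi = size_window
    products = [
        (f, r)
        for f, r in enumerate_products(
            template, fwd_primer, rev_primer, max_mismatch, anchor_3prime
        )
        if lo <= r.end - f.start <= hi
    ]
    if not products:
        raise NoAmplification(template_id)
    if len(products) > 1:
        raise AmbiguousProduct(template_id)
    f, r = products[0]
    return Amplicon(
        template_id=template_id,
        sequence=template[f.start : r.end],
        fwd_site=f,
        rev_site=r,
    )


def amplify_all(
    templates: Iterable[tuple[str, str]],
    fwd_primer: str,
    rev_primer: str,
    size_window: tuple[int, int] = (150, 300),
    max_mismatch: int = 2,
    anchor_3prime: int = 3,
) -> tuple[list[Amplicon], dict[str, str]]:
    """Amplify a batch; failures become per-template statuses, never an
    aborted batch.  Returns (amplicons, {template_id: status})."""
    amplicons: list[Amplicon] = []
    failures: dict[str, str] = {}
    for tid, seq in templates:
        try:
            amplicons.append(
                amplify(
                    tid, seq, fwd_primer, rev_primer, size_window,
                    max_mismatch, anchor_3prime,
                )
            )
        except NoAmplification:
            failures[tid] = "no_amplification"
        except AmbiguousProduct:
            failures[tid] = "ambiguous_product"
    return amplicons, failures


@dataclass
class AmpliconGroup:
    """Templates whose amplicons are exactly identical strings."""

    representative: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def group_by_identity(amplicons: Sequence[Amplicon]) -> list[AmpliconGroup]:
    """Partition amplicons into 100 %-identity groups.

    Groups are sorted by size (desc) then representative sequence so the
    output is invariant to input order; member ids are sorted.
    """
    buckets: dict[str, list[str]] = defaultdict(list)
    for a in amplicons:
        buckets[normalize_seq(a.sequence)].append(a.template_id)
    groups = [
        AmpliconGroup(representative=seq, member_ids=sorted(ids))
        for seq, ids in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.size, g.representative))
    return groups


def pairwise_substitutions(
    group_reps: Sequence[str],
) -> tuple[list[int], np.ndarray]:
    """Polymorphic columns and substitution-count matrix for equal-length
    representative sequences.

    Returns (1-based polymorphic positions, symmetric count matrix with a
    zero diagonal).  Unequal lengths require an externally supplied
    alignment and are rejected here.
    """
    reps = [normalize_seq(r) for r in group_reps]
    if len({len(r) for r in reps}) > 1:
        raise ValueError(
            "representatives differ in length; supply aligned sequences"
        )
    n = len(reps)
    length = len(reps[0]) if reps else 0
    polymorphic = [
        i + 1
        for i in range(length)
        if len({r[i] for r in reps}) > 1
    ]
    matrix = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(1 for a, b in zip(reps[i], reps[j]) if a != b)
            matrix[i, j] = matrix[j, i] = d
    return polymorphic, matrix
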