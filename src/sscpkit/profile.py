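"""Per-column conservation statistics over a nucleotide alignment.

Two column scores drive primer placement:

* **Shannon entropy** over the five states A, T, C, G and gap,
  ``S = -sum_m P(x_m) log P(x_m)`` with ``0 log 0 := 0``.  Ambiguity
  codes carry no state information under this five-state model and are
  excluded from the counts; the ``coverage`` track records the fraction
  of rows that did contribute.
* **Similarity**: the percentage of rows carrying the modal *nucleotide*
  (gaps count in the denominator but can never be the mode).

Entropy is reported in the configured log base (natural log by default);
the upper bound is ``log_base(5)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AMBIGUITY, GAP, STATES, Alignment

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


class UndefinedColumnError(ValueError):
    """Column has no countable residues (empty or all-ambiguous)."""


def _resolve_base(log_base: float | str) -> float:
    if isinstance(log_base, str):
        try:
            return _LOG_BASES[log_base]
        except KeyError:
            raise ValueError(f"log base must be one of {list(_LOG_BASES)}")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log base must be positive and != 1")
    return float(log_base)


def shannon_entropy(column: Sequence[str], log_base: float | str = "e") -> float:
    """Five-state Shannon entropy of one alignment column.

    Parameters
    ----------
    column
        Residue symbols (already normalized: uppercase, U->T).
    log_base
        ``"e"`` (default), ``"2"``, ``"10"`` or any numeric base.

    Raises
    ------
    UndefinedColumnError
        If the column is empty or contains only ambiguity codes.
    """
    if len(column) == 0:
        raise UndefinedColumnError("empty column")
    base = _resolve_base(log_base)
    counts = {s: 0 for s in STATES}
    for sym in column:
        if sym in counts:
            counts[sym] += 1
        elif sym not in AMBIGUITY:
            raise ValueError(f"unknown residue symbol {sym!r}")
    n = sum(counts.values())
    if n == 0:
        raise UndefinedColumnError("column contains only ambiguity codes")
    s = 0.0
    for c in counts.values():
        if c:
            p = c / n
            s -= p * math.log(p)
    return s / math.log(base)


def similarity_percent(column: Sequence[str]) -> float:
    """Percentage of the most frequent nucleotide in one column.

    Gap rows inflate the denominator but are never eligible as the modal
    symbol; ambiguity codes are excluded entirely.
    """
    if len(column) == 0:
        raise UndefinedColumnError("empty column")
    nuc_counts = {s: 0 for s in STATES if s != GAP}
    n = 0
    for sym in column:
        if sym in nuc_counts:
            nuc_counts[sym] += 1
            n += 1
        elif sym == GAP:
            n += 1
        elif sym not in AMBIGUITY:
            raise ValueError(f"unknown residue symbol {sym!r}")
    if n == 0:
        raise UndefinedColumnError("column contains only ambiguity codes")
    modal = max(nuc_counts.values())
    return 100.0 * modal / n


@dataclass
class ConservationProfile:
    """Entropy/similarity/coverage tracks along an alignment.

    Columns are 1-based everywhere the profile is reported.  Columns for
    which a statistic is undefined (all-ambiguous) hold NaN and are
    listed in ``flagged_columns``.
    """

    entropy: np.ndarray
    similarity: np.ndarray
    coverage: np.ndarray
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.entropy = np.asarray(self.entropy, dtype=float)
        self.similarity = np.asarray(self.similarity, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if not (
            len(self.entropy) == len(self.similarity) == len(self.coverage)
        ):
            raise ValueError("profile tracks must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.entropy)

    @property
    def flagged_columns(self) -> list[int]:
        return [int(i) + 1 for i in np.flatnonzero(np.isnan(self.entropy))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "entropy": self.entropy,
                "similarity": self.similarity,
                "coverage": self.coverage,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def conservation_profile(
    aln: Alignment, log_base: float | str = "e"
) -> ConservationProfile:
    """Compute the conservation profile of every column of ``aln``.

    Undefined columns (all ambiguity codes) become NaN rather than
    aborting the whole profile.
    """
    n = aln.length
    ent = np.empty(n)
    sim = np.empty(n)
    cov = np.empty(n)
    for i, col in enumerate(aln.columns()):
        countable = sum(1 for s in col if s in STATES)
        cov[i] = countable / len(col)
        try:
            ent[i] = shannon_entropy(col, log_base)
            sim[i] = similarity_percent(col)
        except UndefinedColumnError:
            ent[i] = np.nan
            sim[i] = np.nan
    base_label = log_base if isinstance(log_base, str) else repr(log_base)
    return ConservationProfile(ent, sim, cov, log_base=base_label)


def plot_profile(profile: ConservationProfile, path: str | Path) -> None:
    """Line plot of similarity (%) and entropy along the alignment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = np.arange(1, profile.n_columns + 1)
    fig, ax1 = plt.subplots(figsize=(10, 3.5))
    ax1.plot(cols, profile.similarity, color="tab:red", lw=0.8, label="similarity (%)")
    ax1.set_xlabel("alignment position")
    ax1.set_ylabel("similarity (%)", color="tab:red")
    ax1.set_ylim(0, 105)
    ax2 = ax1.twinx()
    ax2.plot(cols, profile.entropy, color="tab:blue", lw=0.8, label="entropy")
    ax2.set_ylabel(f"Shannon entropy (log {profile.log_base})", color="tab:blue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
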