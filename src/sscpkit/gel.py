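"""Gel-fingerprint normalization, band-pattern similarity and clustering.

A digitized gel is a table of band positions per lane.  Ladder lanes carry
fragments of known size; fitting migration distance against log10(size)
(Gaussian form by default, log-linear fallback) gives each gel a standard
curve.  Bands from any gel are mapped onto a reference gel's coordinate
scale by inverting the local curve (position -> size) and evaluating the
reference curve (size -> position).  Normalized patterns are compared by
tolerance-matched band counting (Dice by default), clustered by UPGMA on
``100 - similarity``, and the resulting partition can be scored against an
independent grouping (e.g. amplicon sequence identity) with a
chance-adjusted agreement index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

MIN_LADDER_RUNGS = 4
R2_THRESHOLD = 0.95
DEFAULT_TOLERANCE = 4.0

#: sample ids (lower-cased) that mark a lane as a ladder lane in band tables
LADDER_SAMPLE_IDS = frozenset({"ladder", "marker", "m"})


class InsufficientLadder(ValueError):
    """Too few ladder rungs to fit a standard curve."""


class PoorFit(ValueError):
    """Standard curve failed the R-squared acceptance threshold."""


@dataclass
class LadderSpec:
    """Known fragment sizes of the reference ladder, in bp.

    Stored largest-first: larger fragments migrate less, so sizes are
    strictly decreasing with increasing migration distance.
    """

    fragment_sizes: list[float]

    def __post_init__(self) -> None:
        s = list(self.fragment_sizes)
        if len(s) < 2 or any(nxt >= prev for prev, nxt in zip(s, s[1:])):
            raise ValueError("ladder sizes must be strictly decreasing")
        if min(s) <= 0:
            raise ValueError("ladder sizes must be positive")

    @classmethod
    def hundred_bp(cls, max_size: int = 1000) -> "LadderSpec":
        """The standard 100-bp ladder (rungs every 100 bp)."""
        return cls(list(range(max_size, 99, -100)))


@dataclass
class GelLane:
    gel_id: str
    lane_id: str
    bands: list[float]
    intensities: list[float] | None = None
    is_ladder: bool = False
    sample_id: str | None = None

    def __post_init__(self) -> None:
        b = list(self.bands)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(
                f"band positions in {self.gel_id}/{self.lane_id} "
                "must be strictly increasing"
            )
        if self.intensities is not None and len(self.intensities) != len(b):
            raise ValueError("one intensity per band required")


@dataclass
class MigrationCurve:
    """Fitted standard curve: migration distance as a function of
    ``s = log10(fragment size)``."""

    model: str  # "gaussian" | "log_linear"
    params: tuple[float, ...]
    r_squared: float
    size_range: tuple[float, float]  # (min_size, max_size) of the ladder fit

    def distance(self, size: float | np.ndarray) -> float | np.ndarray:
        s = np.log10(size)
        if self.model == "gaussian":
            a, mu, sigma, c = self.params
            return a * np.exp(-((s - mu) ** 2) / (2 * sigma**2)) + c
        a, b = self.params
        return a + b * s

    def size(self, position: float) -> tuple[float, bool]:
        """Invert the curve at ``position``.

        Returns (fragment size, extrapolated).  Inversion is restricted
        to the monotone branch spanned by the ladder; positions outside
        the calibrated range are clamp-extrapolated and flagged.
        """
        lo, hi = self.size_range
        s_lo, s_hi = math.log10(lo), math.log10(hi)
        d_lo = float(self.distance(lo))
        d_hi = float(self.distance(hi))
        # distance decreases with size: d_lo (small frag) > d_hi
        dmin, dmax = min(d_lo, d_hi), max(d_lo, d_hi)
        extrapolated = not (dmin <= position <= dmax)
        if extrapolated:
            target = min(max(position, dmin), dmax)
        else:
            target = position
        f = lambda s: float(self.distance(10**s)) - target
        root = optimize.brentq(f, s_lo, s_hi, xtol=1e-12)
        return 10**root, extrapolated


@dataclass
class NormalizedPattern:
    """Band positions of one lane mapped onto the reference scale."""

    sample_id: str
    positions: np.ndarray
    extrapolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(len(self.positions), dtype=bool)
        else:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if len(self.extrapolated) != len(self.positions):
            raise ValueError("one extrapolation flag per band")

    @property
    def n_bands(self) -> int:
        return len(self.positions)


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def fit_migration_curve(
    ladder_lane: GelLane,
    spec: LadderSpec,
    model: str = "gaussian",
) -> MigrationCurve:
    """Least-squares standard curve from a ladder lane.

    Band positions (increasing migration) are paired with the spec's
    sizes (decreasing).  The caller is responsible for rejecting curves
    with ``r_squared`` below the acceptance threshold (0.95).
    """
    positions = np.asarray(ladder_lane.bands, dtype=float)
    sizes = np.asarray(spec.fragment_sizes, dtype=float)
    if len(positions) != len(sizes):
        raise ValueError(
            f"ladder lane has {len(positions)} bands, spec has {len(sizes)}"
        )
    if len(positions) < MIN_LADDER_RUNGS:
        raise InsufficientLadder(
            f"need >= {MIN_LADDER_RUNGS} rungs, got {len(positions)}"
        )
    s = np.log10(sizes)
    if model == "log_linear":
        b_coef, a_coef = np.polyfit(s, positions, 1)
        params: tuple[float, ...] = (float(a_coef), float(b_coef))
        fitted = a_coef + b_coef * s
    elif model == "gaussian":
        span = positions.max() - positions.min()
        p0 = (2.0 * span, s.min() - 1.0, 1.5, positions.min())
        gauss = lambda s_, a, mu, sigma, c: a * np.exp(
            -((s_ - mu) ** 2) / (2 * sigma**2)
        ) + c
        popt, _ = optimize.curve_fit(gauss, s, positions, p0=p0, maxfev=20000)
        params = tuple(float(x) for x in popt)
        fitted = gauss(s, *popt)
    else:
        raise ValueError(f"unknown migration model {model!r}")
    curve = MigrationCurve(
        model=model,
        params=params,
        r_squared=_r_squared(positions, fitted),
        size_range=(float(sizes.min()), float(sizes.max())),
    )
    # the fitted branch must be monotone across the ladder, or inversion
    # is ill-defined
    grid = np.linspace(s.min(), s.max(), 64)
    d = np.asarray(curve.distance(10**grid))
    if not (np.all(np.diff(d) < 0) or np.all(np.diff(d) > 0)):
        raise ValueError("fitted migration curve is not monotone over the ladder")
    return curve


def normalize_gel(
    gel_lanes: Sequence[GelLane],
    curve: MigrationCurve,
    reference_curve: MigrationCurve,
    require_r2: float = R2_THRESHOLD,
) -> list[NormalizedPattern]:
    """Map every (non-ladder) lane's bands onto the reference gel scale.

    Each band position is inverted through the gel's own curve to a
    fragment size, then pushed through the reference curve.  Bands
    outside the calibrated range are mapped by clamped extrapolation and
    flagged, never dropped.
    """
    for c in (curve, reference_curve):
        if c.r_squared < require_r2:
            raise PoorFit(
                f"standard curve R^2={c.r_squared:.4f} below {require_r2}"
            )
    out = []
    for lane in gel_lanes:
        if lane.is_ladder:
            continue
        positions = []
        flags = []
        for p in lane.bands:
            size, extra = curve.size(p)
            positions.append(float(reference_curve.distance(size)))
            flags.append(extra)
        out.append(
            NormalizedPattern(
                sample_id=lane.sample_id or lane.lane_id,
                positions=np.array(positions),
                extrapolated=np.array(flags, dtype=bool),
            )
        )
    return out


def _max_matching(a: np.ndarray, b: np.ndarray, tolerance: float) -> int:
    """Maximum one-to-one matching of bands within ``tolerance``.

    Both position lists are sorted; eligibility |a_i - b_j| <= tol forms
    an interval bigraph, for which greedy matching in sorted order is
    optimal.
    """
    a = np.sort(a)
    b = np.sort(b)
    i = j = matches = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tolerance:
            matches += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matches


def band_similarity(
    a: NormalizedPattern | Sequence[float],
    b: NormalizedPattern | Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    method: str = "dice",
) -> float:
    """Percent similarity of two band patterns at a position tolerance.

    Bands are matched one-to-one when their positions differ by at most
    ``tolerance`` (reference-scale units), maximizing the match count;
    similarity is 100 * 2m / (nA + nB) (Dice, default) or
    100 * m / (nA + nB - m) (Jaccard).  Two empty patterns are defined
    as 100 (identical absence); one empty vs non-empty is 0.
    """
    pa = a.positions if isinstance(a, NormalizedPattern) else np.asarray(a, float)
    pb = b.positions if isinstance(b, NormalizedPattern) else np.asarray(b, float)
    na, nb = len(pa), len(pb)
    if na == 0 and nb == 0:
        return 100.0
    if na == 0 or nb == 0:
        return 0.0
    m = _max_matching(pa, pb, tolerance)
    if method == "dice":
        return 100.0 * 2 * m / (na + nb)
    if method == "jaccard":
        return 100.0 * m / (na + nb - m)
    raise ValueError(f"unknown similarity method {method!r}")


def similarity_matrix(
    patterns: Sequence[NormalizedPattern],
    tolerance: float = DEFAULT_TOLERANCE,
    method: str = "dice",
) -> pd.DataFrame:
    """Symmetric percent-similarity matrix over patterns."""
    if len(patterns) < 2:
        raise ValueError("need at least two patterns")
    ids = [p.sample_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among patterns")
    n = len(patterns)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = band_similarity(patterns[i], patterns[j], tolerance, method)
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=ids, columns=ids)


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    children = []
    for child in (node.left, node.right):
        sub = _to_newick(child, labels)
        branch = node.dist - (child.dist if not child.is_leaf() else 0.0)
        children.append(f"{sub}:{branch / 2:.6g}")
    # canonical child order: stable output regardless of merge bookkeeping
    return "(" + ",".join(sorted(children)) + ")"


@dataclass
class Dendrogram:
    newick: str
    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, max_distance: float) -> dict[str, int]:
        """Flat clusters at a distance threshold (similarity cut =
        ``100 - max_distance``)."""
        flat = hierarchy.fcluster(self.linkage, t=max_distance, criterion="distance")
        return dict(zip(self.labels, (int(x) for x in flat)))


def upgma_dendrogram(
    sim: pd.DataFrame, linkage_method: str = "average"
) -> Dendrogram:
    """UPGMA (or single/complete) tree from a percent-similarity matrix.

    Clustering operates on distance ``100 - similarity``; leaves are
    ordered lexicographically first so tie-breaking is deterministic.
    """
    mat = sim.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    order = np.argsort(np.asarray(sim.index, dtype=object))
    labels = [str(sim.index[i]) for i in order]
    dist = 100.0 - mat[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    root = hierarchy.to_tree(z)
    newick = _to_newick(root, labels) + ";"
    return Dendrogram(newick=newick, linkage=z, labels=labels)


def compare_partitions(
    cluster_assignment: dict[str, int | str],
    sequence_groups: dict[str, int | str],
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index between two partitions
    of the same samples."""
    missing = sorted(set(sequence_groups) - set(cluster_assignment))
    extra = sorted(set(cluster_assignment) - set(sequence_groups))
    if missing or extra:
        raise ValueError(
            f"sample id mismatch; missing from clustering: {missing}, "
            f"unexpected: {extra}"
        )
    ids = sorted(cluster_assignment)
    left = pd.Series([cluster_assignment[i] for i in ids], name="cluster")
    right = pd.Series([sequence_groups[i] for i in ids], name="group")
    table = pd.crosstab(left, right)
    ari = float(adjusted_rand_score(right, left))
    return table, ari


# ---------------------------------------------------------------- band I/O


def read_band_table(path: str | Path) -> list[GelLane]:
    """Read a band table TSV into lanes.

    Expected columns: ``gel_id, lane_id, sample_id, band_position``
    (optional ``intensity``).  Lanes whose sample_id is 'ladder',
    'marker' or 'M' (case-insensitive) are flagged as ladder lanes.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gel_id", "lane_id", "sample_id", "band_position"}
    if not required <= set(df.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    lanes = []
    for (gel, lane), sub in df.groupby(["gel_id", "lane_id"], sort=True):
        sub = sub.sort_values("band_position")
        sample = str(sub["sample_id"].iloc[0])
        lanes.append(
            GelLane(
                gel_id=str(gel),
                lane_id=str(lane),
                bands=[float(x) for x in sub["band_position"]],
                intensities=(
                    [float(x) for x in sub["intensity"]]
                    if "intensity" in sub.columns and sub["intensity"].notna().all()
                    else None
                ),
                is_ladder=sample.lower() in LADDER_SAMPLE_IDS,
                sample_id=sample,
            )
        )
    return lanes


def write_band_table(lanes: Sequence[GelLane], path: str | Path) -> None:
    rows = []
    for lane in lanes:
        for k, pos in enumerate(lane.bands):
            rows.append(
                {
                    "gel_id": lane.gel_id,
                    "lane_id": lane.lane_id,
                    "sample_id": lane.sample_id
                    or ("ladder" if lane.is_ladder else lane.lane_id),
                    "band_position": pos,
                    "intensity": (
                        lane.intensities[k] if lane.intensities else np.nan
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def normalize_gels(
    lanes: Sequence[GelLane],
    spec: LadderSpec,
    model: str = "gaussian",
    reference_gel: str | None = None,
) -> list[NormalizedPattern]:
    """Fit each gel's ladder curve and normalize every lane onto the
    reference gel (first gel by sorted id unless given)."""
    by_gel: dict[str, list[GelLane]] = {}
    for lane in lanes:
        by_gel.setdefault(lane.gel_id, []).append(lane)
    gel_ids = sorted(by_gel)
    if reference_gel is None:
        reference_gel = gel_ids[0]
    curves = {}
    for gid in gel_ids:
        ladders = [l for l in by_gel[gid] if l.is_ladder]
        if not ladders:
            raise InsufficientLadder(f"gel {gid} has no ladder lane")
        curves[gid] = fit_migration_curve(ladders[0], spec, model)
    ref_curve = curves[reference_gel]
    patterns: list[NormalizedPattern] = []
    for gid in gel_ids:
        patterns.extend(normalize_gel(by_gel[gid], curves[gid], ref_curve))
    return patterns
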