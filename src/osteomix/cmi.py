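"""Cell mixture index (CMI): a 0–1 statistic of two-color spatial mixing.

Foreground pixels of the binarized cyan (osteoblast) and red (osteoclast)
channels become a labeled point set. Agglomerative clustering with Ward's
criterion on the coordinates alone — colors ignored — merges singleton
pixels into ever larger clusters until one remains. At every cluster count
k the size-weighted two-class Gini impurity

    I(k) = sum_c (n_c / N) * (1 - p_cyan,c^2 - p_red,c^2)

is evaluated and normalized by the whole-set impurity g_total = I(1), so the
curve runs from 0 (all singletons, pure) to 1 (one cluster). The CMI is the
trapezoidal area under this normalized impurity plotted against merge
progress x = (N - k)/(N - 1).

Intuition: when the two colors are segregated, early merges build pure
single-color clusters and impurity stays near zero until the final merges —
small AUC. When colors are intermingled, even small local clusters are
mixed, the curve rises immediately, and the AUC approaches 1.

Ward merging uses the centroid Delta-variance cost
Δ(A, B) = |A||B| / (|A|+|B|) * ||mu_A - mu_B||^2 with deterministic
tie-breaking (the candidate pair whose cluster creation indices are
lexicographically smallest), so the merge sequence — including on exactly
symmetric configurations — is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError, DataError, TwoChannelImage
from .preprocess import RATIO_HI, RATIO_LO, BinaryTile, binarize_image, stitch_and_tile

__all__ = [
    "LabeledPointSet",
    "Merge",
    "MergeSequence",
    "ImpurityCurve",
    "CMIResult",
    "points_from_tile",
    "ward_merge_sequence",
    "impurity_curve",
    "cmi_score",
    "compute_cmi",
    "cmi_for_image",
    "DEFAULT_POINT_CAP",
]

#: default cap on points per tile before clustering (naive Ward is O(N^2) memory)
DEFAULT_POINT_CAP = 2000

CYAN, RED = 0, 1


@dataclass
class LabeledPointSet:
    """N spatial points with a binary color label (0 = cyan, 1 = red)."""

    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataError(f"coords must be N×2, got shape {self.coords.shape}")
        if self.labels.shape != (self.coords.shape[0],):
            raise DataError("labels must be one per point")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coords must be finite")
        if not np.all(np.isin(self.labels, (CYAN, RED))):
            raise DataError("labels must be 0 (cyan) or 1 (red)")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_cyan(self) -> int:
        return int(np.sum(self.labels == CYAN))

    @property
    def n_red(self) -> int:
        return int(np.sum(self.labels == RED))


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``a`` and ``b`` (creation-order ids,
    a < b) merge at Ward cost ``cost`` into a cluster of ``size`` points."""

    a: int
    b: int
    cost: float
    size: int


@dataclass
class MergeSequence:
    """The full agglomeration trace of an N-point set.

    Cluster ids follow the linkage convention: 0..N-1 are singletons, merge
    t creates cluster N + t. Membership at any cluster count is recoverable
    by replaying the first N - k merges.
    """

    n: int
    merges: list[Merge] = field(default_factory=list)

    def labels_at(self, k: int) -> np.ndarray:
        """Cluster label per point after merging down to ``k`` clusters."""
        if not 1 <= k <= self.n:
            raise ConfigurationError(f"k must be in [1, {self.n}]")
        parent = np.arange(self.n + len(self.merges))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for t in range(self.n - k):
            m = self.merges[t]
            new = self.n + t
            parent[find(m.a)] = new
            parent[find(m.b)] = new
        roots = np.array([find(i) for i in range(self.n)])
        _, labels = np.unique(roots, return_inverse=True)
        return labels


@dataclass
class ImpurityCurve:
    """Normalized weighted Gini impurity vs merge progress.

    ``x[i] = (N - k_i)/(N - 1)`` for k = N..1 and ``y = I(k)/g_total``; the
    curve starts at (0, 0) — singletons are pure — and ends at (1, 1).
    """

    x: np.ndarray
    y: np.ndarray
    g_total: float


@dataclass
class CMIResult:
    cmi: float
    n_points_used: int
    subsampled: bool
    curve: ImpurityCurve


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def points_from_tile(
    tile: BinaryTile,
    cap: int | None = DEFAULT_POINT_CAP,
    seed: int = 0,
) -> tuple[LabeledPointSet, bool]:
    """One labeled point per foreground pixel; stratified subsample above ``cap``.

    Subsampling draws per color without replacement, preserving the color
    proportions to within one point. Returns (points, subsampled-flag).
    Raises :class:`DataError` when the CMI would be undefined (fewer than two
    points, or one color absent).
    """
    cy = np.argwhere(tile.cyan_mask).astype(np.float64)
    rd = np.argwhere(tile.red_mask).astype(np.float64)
    if len(cy) == 0 or len(rd) == 0:
        raise DataError("CMI undefined: a color is absent from the tile")
    total = len(cy) + len(rd)
    if total < 2:
        raise DataError("CMI undefined: fewer than 2 foreground points")
    subsampled = False
    if cap is not None and total > cap:
        if cap < 2:
            raise ConfigurationError("cap must be >= 2")
        n_cy = int(round(cap * len(cy) / total))
        n_cy = min(max(n_cy, 1), cap - 1)  # keep both colors represented
        n_rd = cap - n_cy
        n_rd = min(n_rd, len(rd))
        n_cy = min(n_cy, len(cy))
        rng = np.random.default_rng(seed)
        cy = cy[rng.choice(len(cy), size=n_cy, replace=False)]
        rd = rd[rng.choice(len(rd), size=n_rd, replace=False)]
        subsampled = True
    coords = np.vstack([cy, rd])
    labels = np.concatenate([np.full(len(cy), CYAN), np.full(len(rd), RED)])
    return LabeledPointSet(coords=coords, labels=labels), subsampled


# ---------------------------------------------------------------------------
# Ward agglomeration
# ---------------------------------------------------------------------------

def _ward_cost_matrix_row(
    centroids: np.ndarray, sizes: np.ndarray, idx: int, active: np.ndarray
) -> np.ndarray:
    diff = centroids[active] - centroids[idx]
    d2 = np.einsum("ij,ij->i", diff, diff)
    na, nk = sizes[idx], sizes[active]
    return (na * nk) / (na + nk) * d2


def ward_merge_sequence(points: LabeledPointSet | np.ndarray) -> MergeSequence:
    """Greedy global-minimum Ward agglomeration of the point coordinates.

    Labels are ignored: clustering is purely spatial. At each of the N - 1
    steps the active pair with minimal Δ-variance cost merges; cost ties are
    broken toward the lexicographically smallest (a, b) pair of cluster
    creation indices.
    """
    coords = points.coords if isinstance(points, LabeledPointSet) else np.asarray(points, float)
    n = coords.shape[0]
    if n < 2:
        raise DataError("need at least 2 points to cluster")

    # slot arrays; merged cluster reuses slot a, slot b dies
    centroids = coords.copy()
    sizes = np.ones(n, dtype=np.float64)
    ids = np.arange(n)  # creation-order id living in each slot
    alive = np.ones(n, dtype=bool)

    # full symmetric cost matrix, inf on diagonal / dead slots
    diff = coords[:, None, :] - coords[None, :, :]
    cost = 0.5 * np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(cost, np.inf)

    merges: list[Merge] = []
    for t in range(n - 1):
        m = cost.min()
        cand = np.argwhere(cost == m)
        cand = cand[cand[:, 0] < cand[:, 1]]
        # tie-break on creation-order id pairs
        keys = np.sort(ids[cand], axis=1)
        best = np.lexsort((keys[:, 1], keys[:, 0]))[0]
        si, sj = cand[best]
        ia, ib = sorted((int(ids[si]), int(ids[sj])))
        new_size = sizes[si] + sizes[sj]
        merges.append(Merge(a=ia, b=ib, cost=float(m), size=int(new_size)))

        centroids[si] = (sizes[si] * centroids[si] + sizes[sj] * centroids[sj]) / new_size
        sizes[si] = new_size
        ids[si] = n + t
        alive[sj] = False
        cost[sj, :] = np.inf
        cost[:, sj] = np.inf
        act = np.flatnonzero(alive & (np.arange(n) != si))
        if act.size:
            row = _ward_cost_matrix_row(centroids, sizes, si, act)
            cost[si, act] = row
            cost[act, si] = row
    return MergeSequence(n=n, merges=merges)


# ---------------------------------------------------------------------------
# Impurity curve and score
# ---------------------------------------------------------------------------

def impurity_curve(points: LabeledPointSet, merges: MergeSequence) -> ImpurityCurve:
    """Normalized weighted Gini impurity at every cluster count k = N..1.

    Uses the incremental update I(k-1) = I(k) - g_a - g_b + g_{a∪b}, where
    g_c = (n_c/N)(1 - p_cyan^2 - p_red^2), so the whole curve costs O(N)
    after clustering.
    """
    if merges.n != points.n:
        raise DataError("merge sequence was not built from this point set")
    n = points.n
    n_cyan_total = points.n_cyan
    if n_cyan_total == 0 or n_cyan_total == n:
        raise DataError("CMI undefined: single-color point set has zero impurity")

    p = n_cyan_total / n
    g_total = 1.0 - p**2 - (1.0 - p) ** 2

    # per-cluster (size, cyan count), indexed by creation-order id
    size = np.zeros(2 * n - 1)
    ncy = np.zeros(2 * n - 1)
    size[:n] = 1.0
    ncy[:n] = (points.labels == CYAN).astype(float)

    def gini_term(cid: int) -> float:
        s = size[cid]
        pc = ncy[cid] / s
        return (s / n) * (1.0 - pc**2 - (1.0 - pc) ** 2)

    y = np.empty(n)
    y[0] = 0.0  # k = N: all singletons pure
    impurity = 0.0
    for t, m in enumerate(merges.merges):
        new = n + t
        size[new] = size[m.a] + size[m.b]
        ncy[new] = ncy[m.a] + ncy[m.b]
        impurity += gini_term(new) - gini_term(m.a) - gini_term(m.b)
        y[t + 1] = impurity / g_total
    x = np.arange(n, dtype=np.float64) / (n - 1)
    y = np.clip(y, 0.0, 1.0)  # guard tiny negative round-off
    return ImpurityCurve(x=x, y=y, g_total=g_total)


def cmi_score(
    curve: ImpurityCurve, *, n_points_used: int | None = None, subsampled: bool = False
) -> CMIResult:
    """Trapezoidal area under the normalized impurity curve."""
    cmi = float(np.trapezoid(curve.y, curve.x))
    return CMIResult(
        cmi=cmi,
        n_points_used=n_points_used if n_points_used is not None else len(curve.x),
        subsampled=subsampled,
        curve=curve,
    )


def compute_cmi(points: LabeledPointSet, *, subsampled: bool = False) -> CMIResult:
    """Cluster, build the impurity curve, and integrate — the full CMI."""
    merges = ward_merge_sequence(points)
    curve = impurity_curve(points, merges)
    return cmi_score(curve, n_points_used=points.n, subsampled=subsampled)


# ---------------------------------------------------------------------------
# Image-level driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CmiConfig:
    """Parameters of the per-tile CMI analysis of a mosaic."""

    tile_grid: tuple[int, int] = (4, 4)
    gamma: float = 1.0
    ratio_lo: float = RATIO_LO
    ratio_hi: float = RATIO_HI
    cap: int | None = DEFAULT_POINT_CAP
    seed: int = 0


def cmi_for_image(
    image: TwoChannelImage | list[TwoChannelImage],
    config: CmiConfig = CmiConfig(),
    field_grid: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-tile CMI table for a stitched mosaic (or a list of fields).

    Runs gamma correction, global per-channel Otsu, tiling, the red/cyan
    ratio filter, then the CMI on every passing tile. The table has one row
    per tile; filtered or degenerate tiles carry a null CMI and a reason.
    """
    if isinstance(image, list):
        if field_grid is None:
            raise ConfigurationError("field_grid is required when passing a field list")
        tiles = stitch_and_tile(
            image, field_grid, config.tile_grid, config.gamma, config.ratio_lo, config.ratio_hi
        )
    else:
        tiles = binarize_image(
            image, config.tile_grid, config.gamma, config.ratio_lo, config.ratio_hi
        )
    rows = []
    for tile in tiles:
        row = {
            "tile_row": tile.tile_index[0],
            "tile_col": tile.tile_index[1],
            "cyan_area_px": tile.cyan_area_px,
            "red_area_px": tile.red_area_px,
            "ratio": tile.ratio,
            "passed_filter": tile.pass_ratio_filter,
            "n_points": np.nan,
            "subsampled": False,
            "cmi": np.nan,
            "reason": "",
        }
        if not tile.pass_ratio_filter:
            row["reason"] = "failed red/cyan ratio filter"
        else:
            try:
                points, sub = points_from_tile(tile, cap=config.cap, seed=config.seed)
                result = compute_cmi(points, subsampled=sub)
                row.update(
                    n_points=result.n_points_used,
                    subsampled=result.subsampled,
                    cmi=result.cmi,
                )
            except DataError as exc:
                row["reason"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out["passed_filter"].any():
        warnings.warn("no tile passed the red/cyan ratio filter; no CMI computed")
    return out
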