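"""Metabolic redundancy grouping of crude extracts from LC-MS feature lists.

Extracts from redundant strains produce near-identical chromatograms.  To avoid
re-working the same chemistry, feature lists (retention time, m/z, intensity)
are discretised onto a fixed RT x m/z grid ("bucketing"), samples become sparse
intensity vectors, pairwise cosine similarities are computed, samples are
ordered by hierarchical clustering, and adjacent samples whose similarity meets
a threshold (default 0.9) are merged into one *metabolic group*.

The m/z axis uses constant-ppm (log-spaced) bins anchored at the range minimum;
the RT axis uses fixed-width bins.  Defaults mirror a 12 s x 5 ppm grid over
30-1080 s and 100-1600 m/z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FeatureList",
    "BucketGrid",
    "BucketTable",
    "MetabolicGrouping",
    "read_feature_csv",
    "bucketize",
    "feature_count_filter",
    "build_bucket_table",
    "cosine_matrix",
    "order_samples",
    "assign_groups",
    "metabolic_grouping",
]


@dataclass(frozen=True)
class FeatureList:
    """Detected LC-MS features of one sample: (rt_s, mz, intensity) triples."""

    sample_id: str
    features: pd.DataFrame  # columns rt_s, mz, intensity

    def __post_init__(self) -> None:
        missing = {"rt_s", "mz", "intensity"} - set(self.features.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class BucketGrid:
    """Fixed RT x m/z grid: linear RT bins, multiplicative (ppm) m/z bins."""

    rt_range_s: tuple[float, float] = (30.0, 1080.0)
    rt_width_s: float = 12.0
    mz_range: tuple[float, float] = (100.0, 1600.0)
    mz_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.rt_width_s <= 0 or self.mz_ppm <= 0:
            raise ValueError("rt_width_s and mz_ppm must be > 0")
        if self.rt_range_s[0] >= self.rt_range_s[1] or self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("empty grid range")

    def rt_bin(self, rt_s: np.ndarray) -> np.ndarray:
        return np.floor((rt_s - self.rt_range_s[0]) / self.rt_width_s).astype(int)

    def mz_bin(self, mz: np.ndarray) -> np.ndarray:
        # constant-ppm bins: edges at mz_min * (1 + ppm*1e-6)^k
        return np.floor(
            np.log(mz / self.mz_range[0]) / math.log1p(self.mz_ppm * 1e-6)
        ).astype(int)

    def in_range(self, rt_s: np.ndarray, mz: np.ndarray) -> np.ndarray:
        return (
            (rt_s >= self.rt_range_s[0]) & (rt_s < self.rt_range_s[1])
            & (mz >= self.mz_range[0]) & (mz < self.mz_range[1])
        )


@dataclass(frozen=True)
class BucketTable:
    """Sample x bucket intensity matrix with the grid it was built on."""

    samples: list[str]
    buckets: list[tuple[int, int]]  # (rt_bin, mz_bin)
    intensities: np.ndarray  # shape (n_samples, n_buckets)
    grid: BucketGrid

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rt{r}_mz{m}" for r, m in self.buckets]
        return pd.DataFrame(self.intensities, index=self.samples, columns=cols)


@dataclass(frozen=True)
class MetabolicGrouping:
    """Leaf-ordered samples, adjacent similarities and group assignments."""

    ordered_samples: list[str]
    consecutive_sims: np.ndarray  # length n-1
    groups: dict[str, int]  # sample -> 1-based contiguous group id
    threshold: float

    @property
    def n_groups(self) -> int:
        return max(self.groups.values()) if self.groups else 0


def read_feature_csv(path, sample_id: str | None = None) -> FeatureList | list[FeatureList]:
    """Read features from CSV.  With a `sample` column, returns one FeatureList
    per sample (long format); otherwise a single list named by ``sample_id``."""
    df = pd.read_csv(path)
    if "sample" in df.columns:
        return [
            FeatureList(sample_id=str(s), features=g[["rt_s", "mz", "intensity"]].reset_index(drop=True))
            for s, g in df.groupby("sample", sort=True)
        ]
    if sample_id is None:
        raise ValueError("sample_id required for single-sample feature CSV")
    return FeatureList(sample_id=sample_id, features=df[["rt_s", "mz", "intensity"]])


def bucketize(fl: FeatureList, grid: BucketGrid) -> tuple[dict[tuple[int, int], float], int]:
    """Sum feature intensities into (rt_bin, mz_bin) buckets.

    Features outside the grid window are dropped and counted, not fatal.
    Intensities are used raw ("no transformation").  Returns (sparse bucket
    vector, number of dropped features).
    """
    rt = fl.features["rt_s"].to_numpy(dtype=float)
    mz = fl.features["mz"].to_numpy(dtype=float)
    inten = fl.features["intensity"].to_numpy(dtype=float)
    ok = grid.in_range(rt, mz)
    dropped = int((~ok).sum())
    vec: dict[tuple[int, int], float] = {}
    for r, m, i in zip(grid.rt_bin(rt[ok]), grid.mz_bin(mz[ok]), inten[ok]):
        key = (int(r), int(m))
        vec[key] = vec.get(key, 0.0) + float(i)
    return vec, dropped


def feature_count_filter(
    feature_lists: list[FeatureList], min_features: int = 50
) -> tuple[list[FeatureList], list[FeatureList]]:
    """Partition samples into (retained, excluded) by feature count.

    Samples with strictly fewer than ``min_features`` detected features carry
    too little signal for a meaningful cosine and are excluded.
    """
    if min_features < 0:
        raise ValueError("min_features must be >= 0")
    retained = [fl for fl in feature_lists if len(fl) >= min_features]
    excluded = [fl for fl in feature_lists if len(fl) < min_features]
    return retained, excluded


def build_bucket_table(
    feature_lists: list[FeatureList], grid: BucketGrid, transform: str | None = None
) -> BucketTable:
    """Bucketize every sample onto a shared grid; drop all-zero bucket columns.

    ``transform='sqrt'`` square-roots bucket intensities before similarity,
    damping base-peak dominance; the default is raw intensities.
    """
    if transform not in (None, "sqrt"):
        raise ValueError("transform must be None or 'sqrt'")
    if not feature_lists:
        raise ValueError("no feature lists given")
    vecs = []
    keys: set[tuple[int, int]] = set()
    for fl in feature_lists:
        vec, _ = bucketize(fl, grid)
        vecs.append(vec)
        keys.update(vec)
    buckets = sorted(keys)
    index = {k: j for j, k in enumerate(buckets)}
    mat = np.zeros((len(feature_lists), len(buckets)))
    for i, vec in enumerate(vecs):
        for k, v in vec.items():
            mat[i, index[k]] = v
    if transform == "sqrt":
        mat = np.sqrt(mat)
    return BucketTable(
        samples=[fl.sample_id for fl in feature_lists],
        buckets=buckets,
        intensities=mat,
        grid=grid,
    )


def cosine_matrix(bt: BucketTable) -> pd.DataFrame:
    """Pairwise cosine similarity S(i,j) = x_i . x_j / (|x_i||x_j|)."""
    if len(bt.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = bt.intensities
    norms = np.linalg.norm(x, axis=1)
    zero = [s for s, nv in zip(bt.samples, norms) if nv == 0]
    if zero:
        raise ValueError(f"zero-intensity sample(s): {zero}; apply feature_count_filter first")
    s = (x @ x.T) / np.outer(norms, norms)
    np.fill_diagonal(s, 1.0)
    s = np.clip(s, 0.0, 1.0)
    return pd.DataFrame(s, index=bt.samples, columns=bt.samples)


def order_samples(similarity: pd.DataFrame, linkage: str = "average") -> list[str]:
    """Dendrogram leaf order from hierarchical clustering on distance 1 - S.

    Sample labels are sorted before clustering so ties in the linkage are
    broken deterministically by label.
    """
    s = similarity.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("similarity matrix must be square and symmetric")
    labels = sorted(similarity.index)
    s = similarity.loc[labels, labels].to_numpy(dtype=float)
    if len(labels) <= 2:
        return list(labels)
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return [labels[i] for i in hierarchy.leaves_list(z)]


def assign_groups(
    ordered_samples: list[str],
    consecutive_sims: np.ndarray | list[float],
    threshold: float = 0.9,
) -> MetabolicGrouping:
    """Walk the leaf order and cut a new group where adjacent similarity drops.

    Adjacent samples with similarity at or above ``threshold`` share a group
    ("0.9 or higher" is inclusive); group ids are contiguous from 1.
    """
    sims = np.asarray(consecutive_sims, dtype=float)
    if sims.size != max(len(ordered_samples) - 1, 0):
        raise ValueError(
            f"expected {len(ordered_samples) - 1} adjacent similarities, got {sims.size}"
        )
    groups: dict[str, int] = {}
    gid = 1 if ordered_samples else 0
    for i, s in enumerate(ordered_samples):
        if i > 0 and sims[i - 1] < threshold:
            gid += 1
        groups[s] = gid
    return MetabolicGrouping(
        ordered_samples=list(ordered_samples),
        consecutive_sims=sims,
        groups=groups,
        threshold=threshold,
    )


def metabolic_grouping(
    feature_lists: list[FeatureList],
    grid: BucketGrid | None = None,
    min_features: int = 50,
    threshold: float = 0.9,
    linkage: str = "average",
    transform: str | None = None,
) -> tuple[MetabolicGrouping, pd.DataFrame, list[str]]:
    """Full pipeline: filter -> bucketize -> cosine -> order -> group.

    Returns (grouping, cosine similarity matrix, excluded sample ids).
    """
    grid = grid or BucketGrid()
    retained, excluded = feature_count_filter(feature_lists, min_features)
    if len(retained) < 2:
        raise ValueError("fewer than 2 samples pass the feature-count filter")
    bt = build_bucket_table(retained, grid, transform=transform)
    sim = cosine_matrix(bt)
    order = order_samples(sim, linkage=linkage)
    sims = np.array([sim.loc[a, b] for a, b in zip(order, order[1:])])
    grouping = assign_groups(order, sims, threshold=threshold)
    return grouping, sim, [fl.sample_id for fl in excluded]
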