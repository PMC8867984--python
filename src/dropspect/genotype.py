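"""Genotype redundancy curation from genomic fingerprint band patterns.

Repetitive-element PCR fingerprints (e.g. BOX-PCR) give each strain a banding
pattern that acts as a strain-level barcode.  Band sizes from different lanes
are first registered onto a shared band registry (electrophoretic sizing is
noisy, so sizes within a relative tolerance are treated as the same band),
fingerprints are compared with the Dice coefficient, clustered with Ward's
method on 1 - Dice, and finally superimposed with the metabolic grouping from
:mod:`dropspect.chemgroup`: strains sharing both a genotype cluster and a
metabolic group are redundant, and one representative per redundancy class is
nominated.

Ward linkage on a non-Euclidean (1 - Dice) dissimilarity is mathematically
informal but standard practice in fingerprint analysis; it is implemented as
the usual Lance-Williams update on the given dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Fingerprint",
    "RedundancyReport",
    "register_bands",
    "dice_similarity",
    "dice_matrix",
    "ward_cluster",
    "cut_clusters",
    "curate",
    "read_band_csv",
]


@dataclass(frozen=True)
class Fingerprint:
    """One strain's band pattern as a set of registry band ids."""

    strain_id: str
    bands: frozenset[int]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"fingerprint for {self.strain_id!r} has no bands")


@dataclass(frozen=True)
class RedundancyReport:
    """Outcome of superimposing genotype clusters with metabolic groups."""

    genotype_clusters: dict[str, int]  # strain -> cluster id
    metabolic_groups: dict[str, int]  # strain -> metabolic group id
    representatives: list[str]  # one nominated strain per (cluster, group) cell
    redundant: dict[str, str]  # redundant strain -> its representative
    unassigned: list[str]  # strains with no metabolic group (flagged, kept)

    @property
    def unique_strains(self) -> list[str]:
        return self.representatives


def read_band_csv(path) -> dict[str, list[float]]:
    """Read long-format CSV ``strain,band_size_bp`` into per-strain size lists."""
    df = pd.read_csv(path)
    return {
        str(s): g["band_size_bp"].astype(float).tolist()
        for s, g in df.groupby("strain", sort=True)
    }


def register_bands(
    raw_sizes: dict[str, list[float]], tolerance: float = 0.02
) -> list[Fingerprint]:
    """Merge band sizes across strains onto a shared registry.

    Single-linkage over the sorted pooled sizes: two adjacent sizes fall into
    the same registry band when their gap is within ``tolerance`` (relative to
    the smaller size).  Each strain's sizes are then mapped to registry ids.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pooled = sorted({float(s) for sizes in raw_sizes.values() for s in sizes})
    if any(s <= 0 for s in pooled):
        raise ValueError("band sizes must be positive")
    band_of: dict[float, int] = {}
    band_id = -1
    prev = None
    for s in pooled:
        if prev is None or (s - prev) > tolerance * prev:
            band_id += 1
        band_of[s] = band_id
        prev = s
    return [
        Fingerprint(strain_id=strain, bands=frozenset(band_of[float(s)] for s in sizes))
        for strain, sizes in sorted(raw_sizes.items())
    ]


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) on band sets."""
    inter = len(a.bands & b.bands)
    return 2.0 * inter / (len(a.bands) + len(b.bands))


def dice_matrix(fingerprints: list[Fingerprint]) -> pd.DataFrame:
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 fingerprints")
    ids = [f.strain_id for f in fingerprints]
    n = len(ids)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = dice_similarity(fingerprints[i], fingerprints[j])
    return pd.DataFrame(s, index=ids, columns=ids)


def ward_cluster(similarity: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward agglomeration on distance 1 - Dice.

    Returns (scipy linkage matrix, leaf labels in input order).  Merge heights
    are non-decreasing by construction of the Ward objective.
    """
    s = similarity.to_numpy(dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(np.clip(d, 0.0, None), checks=False), method="ward")
    return z, list(similarity.index)


def cut_clusters(z: np.ndarray, labels: list[str], cut: float) -> dict[str, int]:
    """Flat clusters at a distance cut; ids renumbered contiguously from 1 in
    order of first appearance of each cluster along the (sorted) label list."""
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, c in zip(labels, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[label] = remap[c]
    return out


def curate(
    genotype_clusters: dict[str, int],
    metabolic_groups: dict[str, int],
) -> RedundancyReport:
    """Superimpose genotype clusters and metabolic groups to nominate uniques.

    Strains sharing *both* a genotype cluster and a metabolic group are
    redundant ("equal"); within each (cluster, group) cell the
    lexicographically smallest strain id is nominated as representative.
    Strains that differ in either dimension stay unique.  Strains with no
    metabolic group are flagged in ``unassigned`` and kept as their own cell.
    """
    if not genotype_clusters:
        raise ValueError("no genotype clusters given")
    cells: dict[tuple[int, object], list[str]] = {}
    unassigned = []
    for strain in sorted(genotype_clusters):
        g = genotype_clusters[strain]
        if strain in metabolic_groups:
            key = (g, metabolic_groups[strain])
        else:
            unassigned.append(strain)
            key = (g, f"unassigned:{strain}")
        cells.setdefault(key, []).append(strain)
    representatives, redundant = [], {}
    for key in sorted(cells, key=lambda k: (k[0], str(k[1]))):
        members = sorted(cells[key])
        representatives.append(members[0])
        for m in members[1:]:
            redundant[m] = members[0]
    return RedundancyReport(
        genotype_clusters=dict(genotype_clusters),
        metabolic_groups=dict(metabolic_groups),
        representatives=representatives,
        redundant=redundant,
        unassigned=unassigned,
    )
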