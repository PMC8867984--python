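"""Community-profile statistics for taxon abundance tables.

Consumes finished amplicon count tables (rows = taxa, columns = samples, as
produced by SILVAngs-style pipelines), applies the pooled relative-abundance
rarity filter, computes Shannon diversity, and compares sample groups with the
Kruskal-Wallis one-way ANOVA on ranks followed by Dunn's post hoc test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CommunityProfile",
    "DiversityResult",
    "read_taxon_table",
    "filter_rare",
    "shannon",
    "shannon_table",
    "kruskal_wallis",
    "dunn_posthoc",
    "significance_stars",
]


@dataclass(frozen=True)
class CommunityProfile:
    """Per-sample taxon read counts at a single taxonomic rank."""

    sample_id: str
    counts: dict[str, int]
    rank: str = "genus"

    def __post_init__(self) -> None:
        for taxon, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for taxon {taxon!r} in {self.sample_id}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float
    richness: int


def read_taxon_table(path, rank: str = "genus") -> list[CommunityProfile]:
    """Read a TSV taxon table (first column taxon label, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        CommunityProfile(sample_id=str(col), counts=df[col].astype(int).to_dict(), rank=rank)
        for col in df.columns
    ]


def filter_rare(
    profiles: list[CommunityProfile], min_rel_abundance: float
) -> tuple[list[CommunityProfile], list[str]]:
    """Drop taxa whose pooled relative abundance is below a threshold.

    "Total" is the grand total of classified reads across the whole table, so a
    taxon is removed from *every* profile when its pooled share is strictly
    below ``min_rel_abundance`` (a fraction, e.g. 1e-5 for 0.001%).  Taxa at
    exactly the threshold are retained.  Returns (filtered profiles, removed
    taxon labels).
    """
    if not profiles:
        raise ValueError("empty profile set")
    if not 0 <= min_rel_abundance < 1:
        raise ValueError("min_rel_abundance must be in [0, 1)")
    pooled: dict[str, int] = {}
    for p in profiles:
        for taxon, c in p.counts.items():
            pooled[taxon] = pooled.get(taxon, 0) + c
    grand_total = sum(pooled.values())
    if grand_total == 0:
        raise ValueError("table has no reads")
    removed = sorted(t for t, c in pooled.items() if c / grand_total < min_rel_abundance)
    removed_set = set(removed)
    filtered = [
        CommunityProfile(
            sample_id=p.sample_id,
            counts={t: c for t, c in p.counts.items() if t not in removed_set},
            rank=p.rank,
        )
        for p in profiles
    ]
    return filtered, removed


def shannon(profile: CommunityProfile, base: float | None = None) -> DiversityResult:
    """Shannon diversity H = -sum p_i log p_i over taxa with nonzero counts.

    Natural log (nats) by default, matching common ecology tooling; pass
    ``base`` to change the logarithm base.
    """
    counts = np.array([c for c in profile.counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError(f"profile {profile.sample_id!r} has no nonzero counts")
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return DiversityResult(sample_id=profile.sample_id, shannon=h, richness=int(counts.size))


def shannon_table(profiles: list[CommunityProfile], base: float | None = None) -> pd.DataFrame:
    rows = [shannon(p, base=base) for p in profiles]
    return pd.DataFrame(
        {"sample": [r.sample_id for r in rows],
         "shannon": [r.shannon for r in rows],
         "richness": [r.richness for r in rows]}
    ).set_index("sample")


def kruskal_wallis(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (one-way ANOVA on ranks) with midrank tie correction.

    Returns (H, p) with p from the chi-square approximation on g-1 degrees of
    freedom.  With identical values everywhere the tie-corrected H is defined
    as 0 (no evidence of a location difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _dunn_pairs(n_groups: int, control: int | None) -> list[tuple[int, int]]:
    if control is None:
        return [(i, j) for i in range(n_groups) for j in range(i + 1, n_groups)]
    return [(control, j) for j in range(n_groups) if j != control]


def dunn_posthoc(
    groups: list[np.ndarray | list[float]],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
    control: int | None = None,
) -> pd.DataFrame:
    """Dunn's post hoc z-tests on pooled midranks after Kruskal-Wallis.

    For each compared pair (all pairs, or every group versus ``control``):

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

    with tie correction T = sum(t^3 - t) over tied value groups.  Two-sided
    normal p-values are adjusted by the configured method (bonferroni, holm,
    or none) and mapped to significance stars.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction over the pooled sample
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())

    mean_ranks, sizes, idx = [], [], 0
    for a in arrays:
        mean_ranks.append(float(ranks[idx: idx + a.size].mean()))
        sizes.append(a.size)
        idx += a.size

    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i, j in _dunn_pairs(len(arrays), control):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if adjust in (None, "none"):
        df["p_adj"] = df["p_raw"]
    else:
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=adjust)[1]
    df["stars"] = [significance_stars(p) for p in df["p_adj"]]
    return df


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to stars: ***<0.001, **<0.01, *<0.1, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return "ns"
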