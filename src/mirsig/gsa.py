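"""Parametric gene-set activity Z-scores and their distribution analyses.

For a contrast with per-gene log2 fold changes, a set of m matched member
genes gets

    z = (S_m - mu) * sqrt(m) / sd_all

where S_m is the mean member fold change and mu, sd_all are the mean and
standard deviation of all fold changes in the contrast.  Under a null contrast
z is approximately standard normal for moderate m, so a positive z means the
set's genes are collectively elevated.  For a miRNA-target (MIR) set, elevated
target genes imply low activity of the corresponding miRNA(s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffexp import ContrastResult
from .io import GeneSetCollection

logger = logging.getLogger("mirsig.gsa")

#: sqrt(m) scaling is unstable for tiny matched sets; smaller sets are skipped.
DEFAULT_MIN_SET_SIZE = 5

QUADRANTS = ("I", "II", "III", "IV", "axis")


@dataclass
class SetActivityProfile:
    """Per-set activity Z-scores for one contrast over one collection."""

    contrast_name: str
    collection_name: str
    set_names: list[str]
    z: np.ndarray
    m: np.ndarray
    skipped: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.set_names, self.z))

    def negated(self) -> "SetActivityProfile":
        return SetActivityProfile(
            contrast_name=f"-{self.contrast_name}",
            collection_name=self.collection_name,
            set_names=list(self.set_names), z=-self.z, m=self.m.copy(),
            skipped=dict(self.skipped),
        )


@dataclass
class RankDistribution:
    """Set Z-scores sorted ascending, with depleted/enriched counts.

    ``x_intercept_rank`` is the 1-based rank of the first non-negative z:
    where the sorted curve crosses zero.
    """

    set_names: list[str]
    z_sorted: np.ndarray
    n_depleted: int
    n_enriched: int
    n_zero: int
    x_intercept_rank: int


def set_zscore(result: ContrastResult, members: list[str],
               min_set_size: int = DEFAULT_MIN_SET_SIZE) -> tuple[float, int]:
    """Activity Z-score of one gene set against a contrast's fold changes.

    Member symbols are matched case-insensitively; unmatched members are
    dropped and the effective size m is returned.  Raises if fewer than
    ``min_set_size`` members match, or if the contrast has zero fold-change
    variance.
    """
    index = result.gene_index()
    rows = [index[g.upper()] for g in dict.fromkeys(m.upper() for m in members)
            if g.upper() in index]
    return _zscore_from_rows(result, np.asarray(rows, dtype=int), min_set_size)


def _zscore_from_rows(result: ContrastResult, rows: np.ndarray,
                      min_set_size: int) -> tuple[float, int]:
    m = len(rows)
    if m < min_set_size:
        raise ValueError(f"only {m} member genes matched; need >= {min_set_size}")
    mu = float(result.fc.mean())
    sd = float(result.fc.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate contrast: zero fold-change variance")
    s_m = float(result.fc[rows].mean())
    return (s_m - mu) * np.sqrt(m) / sd, m


def profile_collection(result: ContrastResult, collection: GeneSetCollection,
                       min_set_size: int = DEFAULT_MIN_SET_SIZE
                       ) -> SetActivityProfile:
    """One Z-score per admissible set of the collection.

    Sets with fewer than ``min_set_size`` matched members are skipped and
    logged; if every set is inadmissible this is a hard error.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    index = result.gene_index()
    mu = float(result.fc.mean())
    sd = float(result.fc.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate contrast: zero fold-change variance")

    names: list[str] = []
    zs: list[float] = []
    ms: list[int] = []
    skipped: dict[str, int] = {}
    for set_name, members in collection.sets.items():
        rows = [index[g] for g in members if g in index]
        m = len(rows)
        if m < min_set_size:
            skipped[set_name] = m
            continue
        s_m = float(result.fc[np.asarray(rows, dtype=int)].mean())
        names.append(set_name)
        zs.append((s_m - mu) * np.sqrt(m) / sd)
        ms.append(m)
    if skipped:
        logger.info("profile_collection(%s/%s): skipped %d set(s) below "
                    "min_set_size=%d", result.name, collection.name,
                    len(skipped), min_set_size)
    if not names:
        raise ValueError("no admissible sets in collection "
                         f"{collection.name!r} (min_set_size={min_set_size})")
    return SetActivityProfile(
        contrast_name=result.name, collection_name=collection.name,
        set_names=names, z=np.asarray(zs), m=np.asarray(ms, dtype=int),
        skipped=skipped,
    )


def rank_distribution(profile: SetActivityProfile) -> RankDistribution:
    """Sort set Z-scores ascending (ties broken by set name) and count the
    depleted (z < 0) and enriched (z > 0) sets."""
    if len(profile.set_names) == 0:
        raise ValueError("empty profile")
    order = sorted(range(len(profile.set_names)),
                   key=lambda i: (profile.z[i], profile.set_names[i]))
    z_sorted = profile.z[order]
    n_dep = int(np.sum(z_sorted < 0))
    n_enr = int(np.sum(z_sorted > 0))
    n_zero = int(np.sum(z_sorted == 0))
    return RankDistribution(
        set_names=[profile.set_names[i] for i in order],
        z_sorted=z_sorted, n_depleted=n_dep, n_enriched=n_enr, n_zero=n_zero,
        x_intercept_rank=n_dep + 1,
    )


@dataclass
class ProfileComparison:
    """Pairwise comparison of two set-activity profiles."""

    pearson_r: float
    p_value: float
    quadrant_counts: dict[str, int]
    n_sets: int


def compare_profiles(profile_a: SetActivityProfile,
                     profile_b: SetActivityProfile) -> ProfileComparison:
    """Pearson r over paired set Z-scores plus per-quadrant counts.

    Sets are matched by name; both profiles must come from the same
    collection.  Quadrant I is (+, +), II (-, +), III (-, -), IV (+, -);
    pairs with a zero coordinate are counted under "axis".
    """
    if profile_a.collection_name != profile_b.collection_name:
        raise ValueError("profiles come from different collections: "
                         f"{profile_a.collection_name!r} vs "
                         f"{profile_b.collection_name!r}")
    zb = profile_b.as_dict()
    pairs = [(za, zb[name]) for name, za in
             zip(profile_a.set_names, profile_a.z) if name in zb]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} shared sets; need >= 3")
    x, y = np.asarray(pairs).T
    fit = stats.linregress(x, y)
    quad = dict.fromkeys(QUADRANTS, 0)
    for xa, ya in pairs:
        if xa == 0 or ya == 0:
            quad["axis"] += 1
        elif xa > 0 and ya > 0:
            quad["I"] += 1
        elif xa < 0 and ya > 0:
            quad["II"] += 1
        elif xa < 0 and ya < 0:
            quad["III"] += 1
        else:
            quad["IV"] += 1
    return ProfileComparison(pearson_r=float(fit.rvalue),
                             p_value=float(fit.pvalue),
                             quadrant_counts=quad, n_sets=len(pairs))


def rank_mirs(profiles: list[SetActivityProfile],
              orientations: list[int]) -> list[tuple[str, float]]:
    """Rank sets by their summed orientation-adjusted Z-score.

    ``orientations`` holds +1/-1 per profile: +1 for a contrast pointing
    toward nc886-high, -1 for a knockdown-style contrast whose Z-scores have
    the opposite sign.  Sets missing from any profile are excluded and logged.
    Returns (set name, score) sorted by descending score, ties by name.
    """
    if len(profiles) != len(orientations):
        raise ValueError("need one orientation per profile")
    if any(o not in (1, -1) for o in orientations):
        raise ValueError("orientations must be +1 or -1")
    collections = {p.collection_name for p in profiles}
    if len(collections) != 1:
        raise ValueError(f"profiles span multiple collections: {collections}")
    maps = [p.as_dict() for p in profiles]
    shared = set(maps[0])
    for m in maps[1:]:
        shared &= set(m)
    excluded = set().union(*maps) - shared
    if excluded:
        logger.info("rank_mirs: excluded %d set(s) missing from some profile",
                    len(excluded))
    scores = {name: sum(o * m[name] for o, m in zip(orientations, maps))
              for name in shared}
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
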