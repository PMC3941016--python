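"""Pairwise genotype similarity: category counting, identity/difference
scoring, all-against-all matrices, and Yates-corrected chi-squared comparison.

At each marker shared by two individuals the genotype pair falls into exactly
one category: MATCH (identical allele multisets, e.g. AA/AA), HALF_MATCH
(exactly one shared allele occurrence, e.g. AT/AA), or CONFLICT (no shared
allele, e.g. CG/AT).  The identity score of a comparison is
matches + half_matches/2 and the difference score conflicts + half_matches/2,
so identity + difference equals the shared-marker total exactly.

No-calls are treated as empty allele multisets: ``--`` against a called
genotype shares nothing (CONFLICT) while ``--`` against ``--`` is identical
(MATCH).  This convention makes the categories partition the full shared
marker set; it is exposed per category so callers can subtract the no-call
contribution if desired.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .genotype_io import GenotypeTable


class ComparisonCategory(Enum):
    MATCH = "match"
    HALF_MATCH = "half_match"
    CONFLICT = "conflict"
    NO_DATA = "no_data"


@dataclass(frozen=True)
class PairwiseComparison:
    """Category counts and identity/difference scores between two individuals."""

    label_a: str
    label_b: str
    matches: int
    half_matches: int
    conflicts: int
    no_data: int = 0

    @property
    def shared_total(self) -> int:
        return self.matches + self.half_matches + self.conflicts

    @property
    def identity(self) -> float:
        return self.matches + self.half_matches / 2.0

    @property
    def difference(self) -> float:
        return self.conflicts + self.half_matches / 2.0

    @property
    def identity_fraction(self) -> float:
        return self.identity / self.shared_total

    @property
    def difference_fraction(self) -> float:
        return self.difference / self.shared_total

    @classmethod
    def from_counts(cls, matches: int, half_matches: int, conflicts: int,
                    label_a: str = "A", label_b: str = "B", no_data: int = 0
                    ) -> "PairwiseComparison":
        return cls(label_a, label_b, matches, half_matches, conflicts, no_data)


@lru_cache(maxsize=None)
def categorize_pair(g1: str, g2: str) -> ComparisonCategory:
    """Categorize two genotype strings at one marker (order-insensitive)."""
    m1, m2 = _multiset(g1), _multiset(g2)
    if m1 == m2:
        return ComparisonCategory.MATCH
    shared = sum((m1 & m2).values())
    if shared == 1:
        return ComparisonCategory.HALF_MATCH
    return ComparisonCategory.CONFLICT


def _multiset(g: str) -> Counter:
    return Counter() if g == "--" else Counter(g)


def categorize_sites(a: GenotypeTable, b: GenotypeTable,
                     chromosome: str | None = None) -> pd.DataFrame:
    """Per-marker categories over the union of two tables' markers.

    Markers present in only one table are labeled NO_DATA.  Returns a frame
    with columns marker_id, chromosome, position, category, sorted by
    genomic coordinate; optionally restricted to one chromosome.
    """
    da, db = a.df, b.df
    if chromosome is not None:
        da = da[da["chromosome"] == chromosome]
        db = db[db["chromosome"] == chromosome]
    m = da.merge(db[["marker_id", "genotype"]], on="marker_id", how="outer",
                 suffixes=("", "_b"))
    only_b = m["chromosome"].isna()
    if only_b.any():
        lut = db.set_index("marker_id")
        ids = m.loc[only_b, "marker_id"]
        m.loc[only_b, "chromosome"] = lut.loc[ids, "chromosome"].to_numpy()
        m.loc[only_b, "position"] = lut.loc[ids, "position"].to_numpy()
    both = m["genotype"].notna() & m["genotype_b"].notna()
    key = m.loc[both, "genotype"] + "|" + m.loc[both, "genotype_b"]
    cat_map = {k: categorize_pair(*k.split("|")) for k in key.unique()}
    cats = pd.Series(ComparisonCategory.NO_DATA, index=m.index, dtype=object)
    cats[both] = key.map(cat_map)
    out = pd.DataFrame({
        "marker_id": m["marker_id"],
        "chromosome": m["chromosome"],
        "position": m["position"].astype(np.int64),
        "category": cats,
    })
    return out.sort_values("position", kind="stable").reset_index(drop=True)


def compare_tables(a: GenotypeTable, b: GenotypeTable) -> PairwiseComparison:
    """Count categories over the marker intersection of two tables."""
    m = a.df[["marker_id", "genotype"]].merge(
        b.df[["marker_id", "genotype"]], on="marker_id", suffixes=("_a", "_b"))
    if m.empty:
        raise ValueError(
            f"no shared markers between {a.individual_label!r} and {b.individual_label!r}")
    key = m["genotype_a"] + "|" + m["genotype_b"]
    cat_map = {k: categorize_pair(*k.split("|")) for k in key.unique()}
    counts = key.map(cat_map).value_counts()
    no_data = (len(a) - len(m)) + (len(b) - len(m))
    return PairwiseComparison(
        label_a=a.individual_label, label_b=b.individual_label,
        matches=int(counts.get(ComparisonCategory.MATCH, 0)),
        half_matches=int(counts.get(ComparisonCategory.HALF_MATCH, 0)),
        conflicts=int(counts.get(ComparisonCategory.CONFLICT, 0)),
        no_data=int(no_data),
    )


def all_against_all(tables: Sequence[GenotypeTable]
                    ) -> Mapping[tuple[str, str], PairwiseComparison]:
    """All self and cross comparisons; keyed by (label_a, label_b), i <= j."""
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    out: dict[tuple[str, str], PairwiseComparison] = {}
    for i, a in enumerate(tables):
        for b in tables[i:]:
            out[(a.individual_label, b.individual_label)] = compare_tables(a, b)
    return out


def identity_matrix(comparisons: Mapping[tuple[str, str], PairwiseComparison]
                    ) -> pd.DataFrame:
    """Symmetric identity-fraction matrix from an all-against-all result."""
    labels = sorted({l for pair in comparisons for l in pair})
    m = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (la, lb), c in comparisons.items():
        m.loc[la, lb] = m.loc[lb, la] = c.identity_fraction
    return m


def _round_half_up(v: float) -> int:
    return math.floor(v + 0.5)


def yates_chisq_similarity(comp_a: PairwiseComparison, comp_b: PairwiseComparison
                           ) -> tuple[float, float]:
    """Pearson chi-squared with Yates continuity correction comparing two
    pairwise similarities.

    Builds the 2x2 table [[identity_a, difference_a], [identity_b,
    difference_b]] with scores rounded half-up to integers, reduces each
    |O - E| by min(0.5, |O - E|), and returns (chi2, p) with 1 degree of
    freedom — the same procedure as R's ``chisq.test`` on a 2x2 table.
    """
    obs = np.array([
        [_round_half_up(comp_a.identity), _round_half_up(comp_a.difference)],
        [_round_half_up(comp_b.identity), _round_half_up(comp_b.difference)],
    ], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero marginal total")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    stat = float((np.maximum(np.abs(obs - expected) - 0.5, 0.0) ** 2 / expected).sum())
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p
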