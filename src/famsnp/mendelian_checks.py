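"""Mendelian-inheritance-error (MIE) detection and hemizygous-deletion
inference from clustered genotype incompatibilities.

A duo MIE is a site where parent and offspring share no allele at all (e.g.
parent TT, child CC) — the only incompatibility detectable from a single
parent-offspring pair.  A trio MIE is a site where no choice of one allele
from each parent reproduces the child's genotype.  Between relatives who are
not parent and offspring, fully incompatible sites are expected from
incomplete genome sharing and are counted as "pseudo-MIEs" with the same
disjoint-allele rule.

A run of duo-incompatible sites clustered in a small genomic interval, with
both individuals reported homozygous throughout, is the signature of a
hemizygous deletion carried by both: over a deleted segment each individual
has one chromosome copy, the chip reports the remaining allele as homozygous,
and wherever the two remaining alleles differ the reported genotypes are
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import pandas as pd

from .genotype_io import GenotypeTable, filter_autosomes

PARENT_OFFSPRING = "parent-offspring duo"
RELATION_TYPES = (PARENT_OFFSPRING, "trio", "sibling", "avuncular", "unrelated")


@dataclass(frozen=True)
class MieReport:
    """Incompatible-site count and coordinates for one relationship."""

    relation_label: str
    relation_type: str
    count: int
    sites: tuple[tuple[str, int, str], ...]  # (chromosome, position, marker_id)

    @property
    def is_mie(self) -> bool:
        """True for direct parent/offspring relations (true MIEs);
        False when the incompatibilities are pseudo-MIEs."""
        return self.relation_type in (PARENT_OFFSPRING, "trio")


@dataclass(frozen=True)
class HemizygousSegment:
    """An inferred hemizygous (deleted) segment shared by parent and offspring."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    carriers: tuple[str, str]
    supporting_sites: int
    spanned_markers: int


def _check_called(*genotypes: str) -> None:
    for g in genotypes:
        if g == "--" or not g:
            raise ValueError("MIE predicates require called genotypes; "
                             "skip no-call sites upstream")


@lru_cache(maxsize=None)
def duo_mie(parent_g: str, child_g: str) -> bool:
    """True iff the child shares no allele with the parent (disjoint allele sets)."""
    _check_called(parent_g, child_g)
    return not (set(parent_g) & set(child_g))


@lru_cache(maxsize=None)
def trio_mie(father_g: str, mother_g: str, child_g: str) -> bool:
    """True iff no transmission of one allele from each parent yields the child."""
    _check_called(father_g, mother_g, child_g)
    child = tuple(sorted(child_g))
    return not any(
        tuple(sorted((fa, ma))) == child
        for fa, ma in product(father_g, mother_g)
    )


def _shared_called(tables: list[GenotypeTable]) -> pd.DataFrame:
    """Inner-join autosomal markers called (non ``--``) in every table."""
    dfs = [filter_autosomes(t).df for t in tables]
    m = dfs[0].rename(columns={"genotype": "g0"})
    for i, d in enumerate(dfs[1:], start=1):
        m = m.merge(d[["marker_id", "genotype"]].rename(columns={"genotype": f"g{i}"}),
                    on="marker_id")
    for i in range(len(tables)):
        m = m[m[f"g{i}"] != "--"]
    if m.empty:
        raise ValueError("no shared called autosomal markers")
    return m.reset_index(drop=True)


def count_mies(table_a: GenotypeTable, table_b: GenotypeTable,
               relation: str = PARENT_OFFSPRING) -> MieReport:
    """Count fully incompatible sites between two individuals.

    ``relation`` declares the relationship (one of ``RELATION_TYPES``); for
    parent-offspring duos the incompatibilities are MIEs proper, otherwise
    pseudo-MIEs.  Only autosomal markers called in both individuals are
    considered; indel (I/D) alleles participate as ordinary alleles.
    """
    if relation not in RELATION_TYPES:
        raise ValueError(f"unknown relation {relation!r}")
    m = _shared_called([table_a, table_b])
    key = m["g0"] + "|" + m["g1"]
    bad_map = {k: duo_mie(*k.split("|")) for k in key.unique()}
    bad = key.map(bad_map)
    hits = m[bad]
    sites = tuple(zip(hits["chromosome"], hits["position"].astype(int), hits["marker_id"]))
    label = f"{table_a.individual_label}/{table_b.individual_label}"
    return MieReport(label, relation, len(sites), sites)


def count_trio_mies(father: GenotypeTable, mother: GenotypeTable,
                    child: GenotypeTable) -> MieReport:
    """Count sites incompatible with any joint transmission from both parents."""
    m = _shared_called([father, mother, child])
    key = m["g0"] + "|" + m["g1"] + "|" + m["g2"]
    bad_map = {k: trio_mie(*k.split("|")) for k in key.unique()}
    hits = m[key.map(bad_map)]
    sites = tuple(zip(hits["chromosome"], hits["position"].astype(int), hits["marker_id"]))
    label = "/".join(t.individual_label for t in (father, mother, child))
    return MieReport(label, "trio", len(sites), sites)


def detect_hemizygous_segments(parent_table: GenotypeTable, child_table: GenotypeTable,
                               min_sites: int = 3, max_gap_bp: int = 50_000
                               ) -> list[HemizygousSegment]:
    """Infer hemizygous deletions shared by a parent-offspring pair.

    Scans each autosome for runs of duo-incompatible sites.  Consecutive
    incompatible sites are merged into one candidate segment when they are at
    most ``max_gap_bp`` apart and no intervening shared site shows a
    heterozygous call in either individual (a het call implies two chromosome
    copies and ends the candidate deletion).  Segments supported by at least
    ``min_sites`` incompatible sites are reported.
    """
    m = _shared_called([parent_table, child_table])
    key = m["g0"] + "|" + m["g1"]
    bad_map = {k: duo_mie(*k.split("|")) for k in key.unique()}
    m["incompatible"] = key.map(bad_map)
    m["any_het"] = (m["g0"].str[0] != m["g0"].str[-1]) | (m["g1"].str[0] != m["g1"].str[-1])

    segments: list[HemizygousSegment] = []
    carriers = (parent_table.individual_label, child_table.individual_label)
    for chrom, grp in m.groupby("chromosome", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        bad = grp["incompatible"].to_numpy()
        het = grp["any_het"].to_numpy()
        cluster: list[int] = []  # indices into grp of supporting sites
        het_since_last = False

        def flush():
            if len(cluster) >= min_sites:
                start, end = int(pos[cluster[0]]), int(pos[cluster[-1]])
                spanned = int(((pos >= start) & (pos <= end)).sum())
                segments.append(HemizygousSegment(
                    chromosome=str(chrom), start=start, end=end, carriers=carriers,
                    supporting_sites=len(cluster), spanned_markers=spanned))

        for i in range(len(grp)):
            if bad[i]:
                if cluster and (het_since_last or pos[i] - pos[cluster[-1]] > max_gap_bp):
                    flush()
                    cluster = []
                cluster.append(i)
                het_since_last = False
            elif het[i]:
                het_since_last = True
        flush()
    return segments


def segments_to_bed(segments: list[HemizygousSegment]) -> str:
    """Render segments as BED text (0-based half-open, from 1-based inclusive)."""
    lines = [
        f"{s.chromosome}\t{s.start - 1}\t{s.end}\t"
        f"{s.carriers[0]}|{s.carriers[1]}\t{s.supporting_sites}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
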