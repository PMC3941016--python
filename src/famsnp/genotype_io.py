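"""Reading, writing and basic manipulation of consumer SNP-chip genotype files.

The raw-download dialect handled here is plain UTF-8 text: ``#``-prefixed header
comments followed by one marker per line with four TAB-separated fields —
marker identifier (dbSNP ``rs…`` or vendor-internal ``i…``), chromosome
(1–22, X, Y, MT), 1-based position and genotype.  A genotype is one or two
allele characters from ``{A, C, G, T, I, D}`` (``I``/``D`` encode insertion and
deletion alleles of indel markers) or the literal ``--`` for a no-call.
"""

from __future__ import annotations

import io
import logging
import re
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical chromosome sort order: autosomes, then X, Y, mitochondrion.
CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
AUTOSOMES = frozenset(str(i) for i in range(1, 23))
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

_GENOTYPE_RE = re.compile(r"^(--|[ACGTID]{1,2})$")


class GenotypeParseError(ValueError):
    """Raised for a malformed genotype file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SnpRecord(NamedTuple):
    """One chip marker: identifier, chromosome, 1-based position, genotype string."""

    marker_id: str
    chromosome: str
    position: int
    genotype: str

    @property
    def is_no_call(self) -> bool:
        return self.genotype == "--"


def normalize_chromosome(token: str) -> str:
    """Normalize a chromosome token (case-insensitive, optional ``chr`` prefix,
    ``M`` accepted for ``MT``).  Raises ``ValueError`` for unknown labels."""
    t = token.strip().upper()
    if t.startswith("CHR"):
        t = t[3:]
    if t == "M":
        t = "MT"
    if t not in _CHROM_RANK:
        raise ValueError(f"unrecognized chromosome {token!r}")
    return t


@dataclass
class GenotypeTable:
    """One individual's ordered marker collection plus provenance metadata.

    ``df`` holds columns ``marker_id``, ``chromosome``, ``position``,
    ``genotype``; rows are sorted by (chromosome order 1..22,X,Y,MT, then
    position) and marker identifiers are unique.
    """

    individual_label: str
    df: pd.DataFrame
    chip_version: str = ""
    assembly: str = "GRCh37"
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.df = _sorted(self.df.reset_index(drop=True))
        dup = self.df["marker_id"].duplicated()
        if dup.any():
            raise GenotypeParseError(
                f"duplicate marker_id {self.df['marker_id'][dup].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[SnpRecord]:
        for row in self.df.itertuples(index=False):
            yield SnpRecord(row.marker_id, row.chromosome, row.position, row.genotype)

    @classmethod
    def from_records(cls, individual_label: str, records: Iterable[SnpRecord], **kw) -> "GenotypeTable":
        df = pd.DataFrame(list(records), columns=["marker_id", "chromosome", "position", "genotype"])
        return cls(individual_label, df, **kw)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Per-genotype-string counts and percentages of a table's records."""

    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    rank = df["chromosome"].map(_CHROM_RANK)
    order = np.lexsort((df["position"].to_numpy(), rank.to_numpy()))
    out = df.iloc[order].reset_index(drop=True)
    out["position"] = out["position"].astype(np.int64)
    return out


def _parse_line(line: str, lineno: int) -> SnpRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 4:
        raise GenotypeParseError(f"expected 4 tab-separated fields, got {len(fields)}", lineno)
    marker_id, chrom, pos, genotype = (f.strip() for f in fields)
    if not marker_id:
        raise GenotypeParseError("empty marker identifier", lineno)
    try:
        chrom = normalize_chromosome(chrom)
    except ValueError as exc:
        raise GenotypeParseError(str(exc), lineno) from None
    try:
        position = int(pos)
    except ValueError:
        raise GenotypeParseError(f"non-integer position {pos!r}", lineno) from None
    if position < 1:
        raise GenotypeParseError(f"position must be >= 1, got {position}", lineno)
    if not _GENOTYPE_RE.match(genotype):
        raise GenotypeParseError(f"illegal genotype {genotype!r}", lineno)
    return SnpRecord(marker_id, chrom, position, genotype)


def read_genotype_file(path, individual_label: str | None = None) -> GenotypeTable:
    """Read a raw genotype text file into a :class:`GenotypeTable`.

    Header comments (``#``-prefixed lines) are preserved as metadata; records
    are sorted into canonical chromosome/position order.  Malformed lines
    raise :class:`GenotypeParseError` naming the line number.
    """
    records: list[SnpRecord] = []
    comments: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#"):
                comments.append(line.rstrip("\n"))
                continue
            records.append(_parse_line(line, lineno))
    label = individual_label if individual_label is not None else str(path)
    return GenotypeTable.from_records(label, records, comments=comments)


def write_genotype_file(table: GenotypeTable, path) -> None:
    """Write ``table`` in the raw dialect; ``read(write(t))`` round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in table.comments:
            fh.write(c + "\n")
        if not table.comments:
            fh.write("# rsid\tchromosome\tposition\tgenotype\n")
        buf = io.StringIO()
        table.df.to_csv(buf, sep="\t", header=False, index=False)
        fh.write(buf.getvalue())


def filter_autosomes(table: GenotypeTable) -> GenotypeTable:
    """Keep only chromosomes 1–22 (X, Y and MT excluded), order preserved."""
    df = table.df[table.df["chromosome"].isin(AUTOSOMES)]
    return GenotypeTable(table.individual_label, df, chip_version=table.chip_version,
                         assembly=table.assembly, comments=list(table.comments))


def no_call_rate(table: GenotypeTable) -> float:
    """Fraction of records with the ``--`` no-call genotype."""
    if len(table) == 0:
        raise ValueError("no_call_rate of an empty table is undefined")
    return float((table.df["genotype"] == "--").mean())


def genotype_distribution(table: GenotypeTable) -> GenotypeDistribution:
    """Counts and percentages of each exact genotype string (AA, AG, ``--``, II, …)."""
    if len(table) == 0:
        raise ValueError("genotype_distribution of an empty table is undefined")
    counts = table.df["genotype"].value_counts()
    total = int(counts.sum())
    return GenotypeDistribution(
        counts={g: int(n) for g, n in counts.items()},
        percentages={g: 100.0 * n / total for g, n in counts.items()},
    )


def intersect_tables(a: GenotypeTable, b: GenotypeTable) -> tuple[GenotypeTable, GenotypeTable]:
    """Restrict both tables to their shared marker identifiers, identically ordered."""
    shared = set(a.df["marker_id"]) & set(b.df["marker_id"])
    out = []
    for t in (a, b):
        df = t.df[t.df["marker_id"].isin(shared)]
        out.append(GenotypeTable(t.individual_label, df, chip_version=t.chip_version,
                                 assembly=t.assembly, comments=list(t.comments)))
    return out[0], out[1]


def merge_tables(a: GenotypeTable, b: GenotypeTable) -> tuple[GenotypeTable, list[str]]:
    """Merge two tables for one individual (e.g. two chip versions).

    The union of markers is returned.  Where both tables call the same marker
    with different non-``--`` genotypes (as unordered allele pairs) the marker
    is reported as a conflict and the first table's call is retained; a ``--``
    is always overridden by a called genotype.  The same marker mapped to
    different coordinates raises ``ValueError``.
    """
    m = a.df.merge(b.df, on="marker_id", how="outer", suffixes=("_a", "_b"), sort=False)
    both = m["genotype_a"].notna() & m["genotype_b"].notna()
    bad = both & ((m["chromosome_a"] != m["chromosome_b"]) | (m["position_a"] != m["position_b"]))
    if bad.any():
        mid = m.loc[bad, "marker_id"].iloc[0]
        raise ValueError(f"marker {mid!r} maps to different coordinates in the two tables")

    def _key(g):
        return "".join(sorted(g)) if isinstance(g, str) and g != "--" else g

    ga, gb = m["genotype_a"], m["genotype_b"]
    conflict_mask = (
        both & (ga != "--") & (gb != "--") & (ga.map(_key) != gb.map(_key))
    )
    conflicts = sorted(m.loc[conflict_mask, "marker_id"])
    genotype = ga.where(ga.notna() & (ga != "--") | gb.isna(), gb)
    out = pd.DataFrame({
        "marker_id": m["marker_id"],
        "chromosome": m["chromosome_a"].fillna(m["chromosome_b"]),
        "position": m["position_a"].fillna(m["position_b"]).astype(np.int64),
        "genotype": genotype,
    })
    merged = GenotypeTable(a.individual_label, out, chip_version=a.chip_version or b.chip_version,
                           assembly=a.assembly, comments=list(a.comments))
    if conflicts:
        logger.warning("%d conflicting genotype(s) between tables: %s",
                       len(conflicts), ", ".join(conflicts[:10]))
    return merged, conflicts


def summarize(table: GenotypeTable, stream=None) -> None:
    """Print record count, no-call rate and genotype distribution."""
    stream = stream or sys.stdout
    print(f"individual:\t{table.individual_label}", file=stream)
    print(f"records:\t{len(table)}", file=stream)
    print(f"no_call_rate:\t{no_call_rate(table):.4%}", file=stream)
    dist = genotype_distribution(table)
    for g in sorted(dist.counts, key=lambda g: -dist.counts[g]):
        print(f"{g}\t{dist.counts[g]}\t{dist.percentages[g]:.2f}%", file=stream)
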