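"""Pedigree genotype simulator emulating consumer SNP-chip family data.

The simulated pedigree mirrors a two-generation family: two grandparent
founders whose children are Mother and her sister (Aunt), an unrelated
founder Father, and two offspring of Father x Mother (Son and Daughter).
Founder haplotypes are drawn marker-by-marker from population allele
frequencies (Hardy-Weinberg, linkage equilibrium); each meiosis lays down a
Poisson number of crossovers per chromosome and transmits a mosaic gamete,
recording which parental copy every marker came from so that the true
inheritance state of any sibling pair is known exactly.

Observed genotypes are produced by the allele-undercall error model: at a
truly heterozygous site the call is NULL with probability x², homozygous for
a uniformly chosen single allele with probability 2x, and correct otherwise;
at a truly homozygous site the call is NULL with probability x.  This is by
construction the same conditional-probability partition the undercall
estimator inverts, so parameter recovery is exact in expectation.  Markers
under a hemizygous deletion carry a single allele, which the chip reports as
homozygous — the signature used for deletion inference.  An optional extra
no-call probability models assay dropout unrelated to allele undercall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable
from .inheritance_states import QUARTET_STATES

#: GRCh37 autosome lengths in bp, for realistic marker panels.
HUMAN_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

#: ~1 cM/Mb, i.e. one expected crossover per 100 Mb per meiosis.
DEFAULT_RECOMB_RATE = 1e-8

#: Default undercall rate: the middle of the range estimated for real chips
#: (0.25%-0.60%), and small enough that NULL' ~ (1-f)x lands near the
#: reported ~0.2% no-call rates.
DEFAULT_ERROR_X = 0.003

FOUNDERS = ("Grandfather", "Grandmother", "Father")
MEMBERS = ("Grandfather", "Grandmother", "Father", "Mother", "Aunt", "Son", "Daughter")
#: (child, father-side parent, mother-side parent)
PEDIGREE = (
    ("Mother", "Grandfather", "Grandmother"),
    ("Aunt", "Grandfather", "Grandmother"),
    ("Son", "Father", "Mother"),
    ("Daughter", "Father", "Mother"),
)
SIBLING_PAIRS = (("Son", "Daughter"), ("Mother", "Aunt"))


@dataclass
class MarkerPanel:
    """Biallelic marker map: coordinates, allele pair and population frequency.

    ``freq`` is the population frequency of the alternate allele; positions
    are strictly increasing within each chromosome and rows are sorted in
    genome order.
    """

    chromosome: np.ndarray  # str labels "1".."22"
    position: np.ndarray    # int64, 1-based
    ref: np.ndarray         # single characters
    alt: np.ndarray
    freq: np.ndarray        # alt-allele frequency in (0, 1)
    chrom_lengths: Mapping[str, int]
    marker_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.marker_ids is None:
            self.marker_ids = np.array([f"rs{i + 1}" for i in range(len(self.position))])

    def __len__(self) -> int:
        return len(self.position)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chromosome.tolist()))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chromosome == chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class Haplotype:
    """Per-marker allele index (0 = ref, 1 = alt) plus hemizygous-deletion mask."""

    alleles: np.ndarray  # uint8
    deleted: np.ndarray  # bool; True where the copy is absent

    def copy(self) -> "Haplotype":
        return Haplotype(self.alleles.copy(), self.deleted.copy())


@dataclass
class MeiosisResult:
    """A gamete, the crossover positions that produced it, and the per-marker
    source copy (0 = parent's first haplotype, 1 = second)."""

    gamete: Haplotype
    crossovers: dict[str, list[int]]
    source: np.ndarray  # uint8


@dataclass(frozen=True)
class Deletion:
    """A hemizygous deletion to plant in one carrier's genome (1-based inclusive)."""

    carrier: str
    chromosome: str
    start: int
    end: int


@dataclass
class SimulatedFamily:
    """Full truth and observations for one simulated pedigree."""

    panel: MarkerPanel
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    meioses: dict[tuple[str, str], MeiosisResult]  # (parent, child) -> result
    true_genotypes: dict[str, np.ndarray]  # sorted allele strings; "" = fully deleted
    tables: dict[str, GenotypeTable]
    deletions: tuple[Deletion, ...]
    deletion_haplotype: dict[int, int]  # deletion index -> carrier haplotype index
    error_x: float
    nocall_extra: float
    recomb_rate: float
    seed: int | None

    def true_state_codes(self, pair: tuple[str, str]) -> np.ndarray:
        """Per-marker true inheritance state (index into QUARTET_STATES) for a
        sibling pair, derived from the transmitted-copy labels."""
        c1, c2 = pair
        pf = pm = None
        for child, fa, mo in PEDIGREE:
            if child == c1:
                pf, pm = fa, mo
        pat_same = self.meioses[(pf, c1)].source == self.meioses[(pf, c2)].source
        mat_same = self.meioses[(pm, c1)].source == self.meioses[(pm, c2)].source
        codes = np.full(len(self.panel), 3, dtype=np.uint8)  # NONIDENTICAL
        codes[pat_same & mat_same] = 0
        codes[~pat_same & mat_same] = 1  # same maternal copy only
        codes[pat_same & ~mat_same] = 2  # same paternal copy only
        return codes

    def true_states(self, pair: tuple[str, str]) -> np.ndarray:
        return np.array(QUARTET_STATES, dtype=object)[self.true_state_codes(pair)]

    def quartet_crossovers(self) -> dict[str, list[int]]:
        """All crossover positions, per chromosome, of the four meioses that
        produced Son and Daughter (block boundaries of the true state track)."""
        out: dict[str, list[int]] = {c: [] for c in self.panel.chromosomes}
        for (parent, child), res in self.meioses.items():
            if child in ("Son", "Daughter"):
                for chrom, xs in res.crossovers.items():
                    out[chrom].extend(xs)
        return {c: sorted(v) for c, v in out.items()}


def make_panel(n_snps: int, n_chromosomes: int = 22,
               chrom_length: int | Sequence[int] | Mapping[str, int] = 130_000_000,
               freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | float | None = None,
               seed: int | None = None) -> MarkerPanel:
    """Build a random marker panel.

    Markers are placed uniformly over the genome (chromosomes weighted by
    length) and sorted; alternate-allele frequencies come from
    ``freq_sampler`` (a callable ``(rng, n) -> array``, a constant, or the
    default Uniform(0.05, 0.95)).  Pass ``HUMAN_AUTOSOME_LENGTHS`` as
    ``chrom_length`` for a realistic genome.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_snps < n_chromosomes:
        raise ValueError("need at least one marker per chromosome (n_snps >= n_chromosomes)")
    rng = np.random.default_rng(seed)
    if isinstance(chrom_length, Mapping):
        labels = list(chrom_length)
        lengths = np.array([chrom_length[c] for c in labels], dtype=np.int64)
        if n_chromosomes != len(labels):
            labels, lengths = labels[:n_chromosomes], lengths[:n_chromosomes]
    else:
        labels = [str(i) for i in range(1, n_chromosomes + 1)]
        if np.isscalar(chrom_length):
            lengths = np.full(n_chromosomes, int(chrom_length), dtype=np.int64)
        else:
            lengths = np.asarray(chrom_length, dtype=np.int64)
            if len(lengths) != n_chromosomes:
                raise ValueError("chrom_length sequence must have n_chromosomes entries")

    chrom_idx = rng.choice(n_chromosomes, size=n_snps, p=lengths / lengths.sum())
    chroms, positions = [], []
    for i, label in enumerate(labels):
        k = int((chrom_idx == i).sum())
        if k == 0:
            continue
        pos = np.unique(rng.integers(1, lengths[i] + 1, size=k))
        while len(pos) < k:  # redraw collisions; rare for realistic lengths
            extra = rng.integers(1, lengths[i] + 1, size=k - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(k, label))
        positions.append(pos)
    chromosome = np.concatenate(chroms)
    position = np.concatenate(positions).astype(np.int64)

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    if freq_sampler is None:
        freq = rng.uniform(0.05, 0.95, size=n_snps)
    elif callable(freq_sampler):
        freq = np.asarray(freq_sampler(rng, n_snps), dtype=float)
    else:
        freq = np.full(n_snps, float(freq_sampler))
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return MarkerPanel(chromosome=chromosome, position=position,
                       ref=bases[ref_i], alt=bases[alt_i], freq=freq,
                       chrom_lengths=dict(zip(labels, lengths.tolist())))


def _draw_founder(panel: MarkerPanel, rng: np.random.Generator
                  ) -> tuple[Haplotype, Haplotype]:
    n = len(panel)
    return tuple(
        Haplotype((rng.random(n) < panel.freq).astype(np.uint8),
                  np.zeros(n, dtype=bool))
        for _ in range(2)
    )


def simulate_meiosis(parent_haplotypes: tuple[Haplotype, Haplotype],
                     panel: MarkerPanel,
                     recomb_rate_per_bp: float = DEFAULT_RECOMB_RATE,
                     seed: int | np.random.Generator | None = None) -> MeiosisResult:
    """Generate one gamete from a pair of parental haplotypes.

    Per chromosome the crossover count is Poisson(rate x length), crossover
    positions are uniform, and the starting haplotype is chosen uniformly; a
    crossover at position p switches the source copy for all markers with
    position > p.
    """
    if recomb_rate_per_bp < 0:
        raise ValueError("recombination rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h1, h2 = parent_haplotypes
    n = len(panel)
    source = np.zeros(n, dtype=np.uint8)
    crossovers: dict[str, list[int]] = {}
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        length = panel.chrom_lengths[chrom]
        k = rng.poisson(recomb_rate_per_bp * length)
        xpos = np.sort(rng.integers(1, length + 1, size=k))
        start = rng.integers(0, 2)
        crossings = np.searchsorted(xpos, panel.position[sl], side="left")
        source[sl] = (start + crossings) % 2
        crossovers[chrom] = xpos.tolist()
    gamete = Haplotype(np.where(source == 0, h1.alleles, h2.alleles),
                       np.where(source == 0, h1.deleted, h2.deleted))
    return MeiosisResult(gamete=gamete, crossovers=crossovers, source=source)


def apply_error_model(true_genotype: str, x: float,
                      seed: int | np.random.Generator | None = None) -> str:
    """Apply the undercall error model to one true genotype string.

    Heterozygous truth: NULL w.p. x², homozygous for a uniformly chosen
    allele w.p. 2x, correct otherwise.  Homozygous truth: NULL w.p. x.
    Hemizygous truth (single character): reported homozygous for the present
    allele, or NULL w.p. x.  Fully deleted truth (empty string): NULL.
    """
    if not 0.0 <= x <= 0.414:
        raise ValueError("x outside [0, sqrt(2)-1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if true_genotype in ("", "--"):
        return "--"
    if len(true_genotype) == 1:
        return "--" if rng.random() < x else true_genotype * 2
    a, b = true_genotype
    u = rng.random()
    if a == b:
        return "--" if u < x else true_genotype
    if u < x * x:
        return "--"
    if u < x * x + 2 * x:
        kept = a if rng.random() < 0.5 else b
        return kept * 2
    return "".join(sorted((a, b)))


def _observe(panel: MarkerPanel, hap_pair: tuple[Haplotype, Haplotype], x: float,
             nocall_extra: float, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized error model over one individual's haplotype pair.

    Returns (true genotype strings, observed genotype strings); allele
    characters are alphabetically sorted, hemizygous truths are single
    characters, fully deleted truths are empty strings.
    """
    h1, h2 = hap_pair
    c1 = np.where(h1.alleles == 0, panel.ref, panel.alt)
    c2 = np.where(h2.alleles == 0, panel.ref, panel.alt)
    swap = c1 > c2
    lo, hi = np.where(swap, c2, c1), np.where(swap, c1, c2)
    d1, d2 = h1.deleted, h2.deleted

    truth = np.char.add(lo, hi)
    hemi = d1 ^ d2
    present = np.where(d1, c2, c1)
    truth[hemi] = present[hemi]
    truth[d1 & d2] = ""

    n = len(panel)
    u = rng.random(n)
    pick_first = rng.random(n) < 0.5  # which allele survives a het undercall
    obs = truth.copy()

    het = ~d1 & ~d2 & (c1 != c2)
    hom = ~d1 & ~d2 & (c1 == c2)
    obs[het & (u < x * x)] = "--"
    dropped = het & (u >= x * x) & (u < x * x + 2 * x)
    kept = np.where(pick_first, lo, hi)
    obs[dropped] = np.char.add(kept, kept)[dropped]
    obs[hom & (u < x)] = "--"
    obs[hemi] = np.char.add(present, present)[hemi]
    obs[hemi & (u < x)] = "--"
    obs[d1 & d2] = "--"
    if nocall_extra > 0:
        obs[rng.random(n) < nocall_extra] = "--"
    return truth, obs


def _table_from(panel: MarkerPanel, label: str, observed: np.ndarray) -> GenotypeTable:
    df = pd.DataFrame({
        "marker_id": panel.marker_ids,
        "chromosome": panel.chromosome,
        "position": panel.position,
        "genotype": observed,
    })
    return GenotypeTable(label, df, chip_version="simulated", assembly="synthetic",
                         comments=[f"# simulated genotypes for {label}"])


def simulate_family(panel: MarkerPanel,
                    recomb_rate: float = DEFAULT_RECOMB_RATE,
                    error_x: float = DEFAULT_ERROR_X,
                    nocall_extra: float = 0.0,
                    deletions: Sequence[Deletion] = (),
                    seed: int | None = None) -> SimulatedFamily:
    """Simulate the full seven-member pedigree with truth bookkeeping.

    Founder genotypes follow Hardy-Weinberg at the panel frequencies;
    non-founders arise by simulated meioses.  Deletions are planted on a
    fair-coin-chosen haplotype of their named carrier before that carrier's
    gametes are drawn, so transmission to each child follows mendelian
    segregation of the carrying haplotype.
    """
    ss = np.random.SeedSequence(seed)
    rng_founders, rng_meiosis, rng_errors, rng_struct = (
        np.random.default_rng(s) for s in ss.spawn(4))

    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {
        name: _draw_founder(panel, rng_founders) for name in FOUNDERS
    }
    deletion_haplotype: dict[int, int] = {}

    def plant_deletions(member: str) -> None:
        for i, dl in enumerate(deletions):
            if dl.carrier != member:
                continue
            mask = ((panel.chromosome == dl.chromosome)
                    & (panel.position >= dl.start) & (panel.position <= dl.end))
            if not mask.any():
                warnings.warn(f"deletion {dl} spans no panel markers")
            hap_idx = int(rng_struct.integers(0, 2))
            deletion_haplotype[i] = hap_idx
            haplotypes[member][hap_idx].deleted[mask] = True

    meioses: dict[tuple[str, str], MeiosisResult] = {}
    for member in FOUNDERS:
        plant_deletions(member)
    # PEDIGREE order guarantees Mother's deletions are planted before her
    # gametes to Son/Daughter are drawn.
    for child, fa, mo in PEDIGREE:
        mp = simulate_meiosis(haplotypes[fa], panel, recomb_rate, rng_meiosis)
        mm = simulate_meiosis(haplotypes[mo], panel, recomb_rate, rng_meiosis)
        meioses[(fa, child)] = mp
        meioses[(mo, child)] = mm
        haplotypes[child] = (mp.gamete, mm.gamete)
        plant_deletions(child)

    true_genotypes: dict[str, np.ndarray] = {}
    tables: dict[str, GenotypeTable] = {}
    for member in MEMBERS:
        truth, obs = _observe(panel, haplotypes[member], error_x, nocall_extra, rng_errors)
        true_genotypes[member] = truth
        tables[member] = _table_from(panel, member, obs)

    return SimulatedFamily(panel=panel, haplotypes=haplotypes, meioses=meioses,
                           true_genotypes=true_genotypes, tables=tables,
                           deletions=tuple(deletions),
                           deletion_haplotype=deletion_haplotype,
                           error_x=error_x, nocall_extra=nocall_extra,
                           recomb_rate=recomb_rate, seed=seed)


def write_family(family: SimulatedFamily, outdir) -> None:
    """Write one raw-dialect genotype file per member plus a truth manifest.

    The manifest (``truth.tsv``) is tabular text with one section per record
    kind: crossover positions per meiosis, per-sibling-pair state-block
    summaries, and planted deletions.
    """
    from pathlib import Path
    from .genotype_io import write_genotype_file

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in family.tables.items():
        write_genotype_file(table, out / f"{name}.txt")
    rows = []
    for (parent, child), res in family.meioses.items():
        for chrom, xs in res.crossovers.items():
            for p in xs:
                rows.append(("crossover", f"{parent}>{child}", chrom, p, ""))
    for i, dl in enumerate(family.deletions):
        rows.append(("deletion", dl.carrier, dl.chromosome, dl.start,
                     f"end={dl.end};haplotype={family.deletion_haplotype.get(i, '')}"))
    for pair in SIBLING_PAIRS:
        codes = family.true_state_codes(pair)
        change = np.flatnonzero(np.diff(codes.astype(int)) != 0)
        rows.append(("state_blocks", "/".join(pair), "genome-wide",
                     int(len(change) + 1), "marker-resolution block count"))
    manifest = pd.DataFrame(rows, columns=["record", "who", "chromosome", "value", "extra"])
    manifest.to_csv(out / "truth.tsv", sep="\t", index=False)
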