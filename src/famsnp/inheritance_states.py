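"""Inheritance State Consistency Analysis (ISCA) for two-offspring quartets.

At every autosomal site, two siblings either inherited the same parental
chromosome copy from both parents ("identical"), the same copy from exactly
one parent ("haploidentical", maternal or paternal according to which parent
transmitted the shared copy), or different copies from both ("nonidentical").
States are defined by transmitted-*copy* equality, not allele-value equality:
a parent homozygous at a site transmits the same allele value either way, so
such sites carry no information about that parent's transmission.

A site's *consistent-state set* is found by enumerating the 16 labeled
transmission choices (father's copy 1 or 2 to each child x mother's copy 1
or 2 to each child) and keeping the states of every choice that reproduces
both children's genotypes.  A site consistent with a single state contributes
weight 1 to it; with exactly two states, weight 0.5 to each; with three or
more it is non-informative and contributes nothing.  An empty set means the
observed genotypes are impossible under any transmission — a genotyping
error ("state-consistency error").  Weights accumulated in non-overlapping
1 Mb windows reveal contiguous inheritance blocks bounded by recombination
events; the fraction of the genome in each state is expected to be near 25%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, filter_autosomes


class InheritanceState(Enum):
    IDENTICAL = "identical"
    HAPLOIDENTICAL_MATERNAL = "haploidentical_maternal"
    HAPLOIDENTICAL_PATERNAL = "haploidentical_paternal"
    NONIDENTICAL = "nonidentical"
    #: merged haploidentical state for the missing-parents sibling mode
    HAPLOIDENTICAL = "haploidentical"


QUARTET_STATES = (
    InheritanceState.IDENTICAL,
    InheritanceState.HAPLOIDENTICAL_MATERNAL,
    InheritanceState.HAPLOIDENTICAL_PATERNAL,
    InheritanceState.NONIDENTICAL,
)

_TRANSMISSIONS = tuple(product((0, 1), repeat=4))  # (i1, i2, j1, j2)


def _state_of(i1: int, i2: int, j1: int, j2: int) -> InheritanceState:
    pat_same, mat_same = i1 == i2, j1 == j2
    if pat_same and mat_same:
        return InheritanceState.IDENTICAL
    if mat_same:
        return InheritanceState.HAPLOIDENTICAL_MATERNAL
    if pat_same:
        return InheritanceState.HAPLOIDENTICAL_PATERNAL
    return InheritanceState.NONIDENTICAL


def _check_diploid(*genotypes: str) -> None:
    for g in genotypes:
        if g == "--" or len(g) != 2:
            raise ValueError(f"ISCA requires called diploid genotypes, got {g!r}")


@lru_cache(maxsize=None)
def consistent_states(father_g: str, mother_g: str, child1_g: str, child2_g: str
                      ) -> frozenset[InheritanceState]:
    """States consistent with the observed quartet genotypes at one site.

    An empty set flags a state-consistency error (no transmission explains
    the children).
    """
    _check_diploid(father_g, mother_g, child1_g, child2_g)
    F, M = tuple(father_g), tuple(mother_g)
    c1, c2 = tuple(sorted(child1_g)), tuple(sorted(child2_g))
    states = set()
    for i1, i2, j1, j2 in _TRANSMISSIONS:
        if (tuple(sorted((F[i1], M[j1]))) == c1
                and tuple(sorted((F[i2], M[j2]))) == c2):
            states.add(_state_of(i1, i2, j1, j2))
    return frozenset(states)


@lru_cache(maxsize=None)
def sibling_states_missing_parents(sib1_g: str, sib2_g: str,
                                   allele_universe: tuple[str, ...] | None = None
                                   ) -> frozenset[InheritanceState]:
    """Consistent states for a sibling pair whose parents are unobserved.

    Both parents' genotypes are additionally enumerated over the allele
    universe of the site (default: the alleles observed in the two siblings,
    biallelic assumption).  Without parental genotypes the two haploidentical
    states cannot be told apart and are merged into
    :data:`InheritanceState.HAPLOIDENTICAL`.
    """
    _check_diploid(sib1_g, sib2_g)
    if allele_universe is None:
        universe = tuple(sorted(set(sib1_g) | set(sib2_g)))
    else:
        universe = tuple(sorted(set(allele_universe)))
    merge = {
        InheritanceState.HAPLOIDENTICAL_MATERNAL: InheritanceState.HAPLOIDENTICAL,
        InheritanceState.HAPLOIDENTICAL_PATERNAL: InheritanceState.HAPLOIDENTICAL,
    }
    states = set()
    for F in product(universe, repeat=2):
        for M in product(universe, repeat=2):
            for s in consistent_states("".join(F), "".join(M), sib1_g, sib2_g):
                states.add(merge.get(s, s))
    return frozenset(states)


@dataclass
class StateSupportTrack:
    """Binned weighted support for the four quartet inheritance states.

    ``bins`` has one row per (chromosome, bin) with weight columns ``w_id``,
    ``w_hm``, ``w_hp``, ``w_ni``, the informative-marker count, and the
    argmax state (NaN where no informative weight fell in the bin).
    """

    bins: pd.DataFrame
    bin_bp: int
    n_sites: int
    n_error_sites: int  # sites with an empty consistent set

    @property
    def assigned(self) -> pd.DataFrame:
        return self.bins[self.bins["argmax"].notna()]


_WEIGHT_COLS = {
    InheritanceState.IDENTICAL: "w_id",
    InheritanceState.HAPLOIDENTICAL_MATERNAL: "w_hm",
    InheritanceState.HAPLOIDENTICAL_PATERNAL: "w_hp",
    InheritanceState.NONIDENTICAL: "w_ni",
}


def build_state_track(father: GenotypeTable, mother: GenotypeTable,
                      child1: GenotypeTable, child2: GenotypeTable,
                      bin_bp: int = 1_000_000) -> StateSupportTrack:
    """Accumulate per-site state support into non-overlapping genomic bins.

    Sites are the autosomal markers shared by all four tables with called
    diploid genotypes in every individual.  Each site contributes weight 1
    to a singleton consistent set, 0.5 to each of a pair, and 0 otherwise.
    """
    dfs = []
    for name, t in (("f", father), ("m", mother), ("c1", child1), ("c2", child2)):
        d = filter_autosomes(t).df
        dfs.append(d[["marker_id", "chromosome", "position", "genotype"]]
                   .rename(columns={"genotype": name}))
    m = dfs[0]
    for d in dfs[1:]:
        m = m.merge(d[["marker_id", d.columns[-1]]], on="marker_id")
    ok = np.ones(len(m), dtype=bool)
    for col in ("f", "m", "c1", "c2"):
        ok &= (m[col] != "--").to_numpy() & (m[col].str.len() == 2).to_numpy()
    m = m[ok]
    if m.empty:
        raise ValueError("no shared, fully called autosomal markers in the quartet")

    key = m["f"] + "|" + m["m"] + "|" + m["c1"] + "|" + m["c2"]
    weights_of: dict[str, tuple[float, float, float, float]] = {}
    for k in key.unique():
        states = consistent_states(*k.split("|"))
        w = [0.0, 0.0, 0.0, 0.0]
        if len(states) == 1:
            w[QUARTET_STATES.index(next(iter(states)))] = 1.0
        elif len(states) == 2:
            for s in states:
                w[QUARTET_STATES.index(s)] = 0.5
        weights_of[k] = tuple(w)

    wmat = np.array([weights_of[k] for k in key], dtype=float)
    err = ~wmat.any(axis=1) & key.map(
        lambda k: len(consistent_states(*k.split("|"))) == 0).to_numpy()
    binned = pd.DataFrame({
        "chromosome": m["chromosome"].to_numpy(),
        "bin": m["position"].to_numpy() // bin_bp,
        "w_id": wmat[:, 0], "w_hm": wmat[:, 1],
        "w_hp": wmat[:, 2], "w_ni": wmat[:, 3],
    })
    binned["informative"] = (wmat.sum(axis=1) > 0).astype(int)
    agg = binned.groupby(["chromosome", "bin"], sort=False).sum().reset_index()

    wcols = ["w_id", "w_hm", "w_hp", "w_ni"]
    warr = agg[wcols].to_numpy()
    top = warr.max(axis=1)
    # a bin is assigned only when a single state holds the top support; a tie
    # carries no majority evidence (it arises in near-empty partial bins)
    unique_top = (warr == top[:, None]).sum(axis=1) == 1
    assigned = (top > 0) & unique_top
    argmax = pd.Series(pd.NA, index=agg.index, dtype=object)
    argmax[assigned] = [QUARTET_STATES[i] for i in warr[assigned].argmax(axis=1)]
    agg["argmax"] = argmax
    agg = agg.rename(columns={"informative": "n_informative"})
    return StateSupportTrack(bins=agg, bin_bp=bin_bp, n_sites=len(m),
                             n_error_sites=int(err.sum()))


def genome_state_fractions(track: StateSupportTrack) -> dict[InheritanceState, float]:
    """Fraction of assigned bins whose top-supported state is each state."""
    assigned = track.assigned
    if assigned.empty:
        raise ValueError("no assigned bins in the track")
    counts = assigned["argmax"].value_counts()
    total = int(counts.sum())
    return {s: float(counts.get(s, 0)) / total for s in QUARTET_STATES}


def plot_state_track(track: StateSupportTrack, out_path, chromosomes=None) -> None:
    """Stacked per-bin state-support plot, one panel per chromosome.

    Within each bin the four state weights are drawn as a stacked bar
    (identical red, haploidentical maternal green, haploidentical paternal
    yellow, nonidentical blue).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"w_id": "red", "w_hm": "green", "w_hp": "gold", "w_ni": "blue"}
    chroms = chromosomes or list(dict.fromkeys(track.bins["chromosome"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.2 * len(chroms)),
                             squeeze=False, sharex=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        grp = track.bins[track.bins["chromosome"] == chrom].sort_values("bin")
        bottom = np.zeros(len(grp))
        for col, color in colors.items():
            ax.bar(grp["bin"], grp[col], bottom=bottom, width=1.0, color=color)
            bottom += grp[col].to_numpy()
        ax.set_ylabel(str(chrom), rotation=0, labelpad=15)
        ax.set_yticks([])
    axes[-1, 0].set_xlabel(f"bin ({track.bin_bp} bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def state_switch_bins(track: StateSupportTrack) -> list[tuple[str, int]]:
    """(chromosome, bin) locations where the per-bin argmax state changes.

    The reported bin is the first bin of the new state; unassigned bins are
    skipped when determining the previous state.
    """
    switches: list[tuple[str, int]] = []
    for chrom, grp in track.assigned.groupby("chromosome", sort=False):
        grp = grp.sort_values("bin")
        prev = None
        for b, s in zip(grp["bin"], grp["argmax"]):
            if prev is not None and s != prev:
                switches.append((str(chrom), int(b)))
            prev = s
    return switches
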