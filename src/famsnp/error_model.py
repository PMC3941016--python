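"""Heterozygote-undercall estimation from observed call-class proportions.

Model: every eligible marker is biallelic and diploid, each truly present
allele is independently *not observed* with probability ``x`` (the undercall
rate), and no wrong allele is ever observed.  A truly heterozygous site is
then reported NULL (no-call) with probability x², homozygous with probability
2x and heterozygous with probability 1 − 2x − x²; a truly homozygous site is
reported NULL with probability x and homozygous otherwise.  With ``f`` the
true heterozygous fraction of the N eligible markers, the expected observed
class frequencies are

    NULL' = f·x² + (1 − f)·x
    HET'  = f·(1 − 2x − x²)
    HOM'  = (1 − f)(1 − x) + 2·f·x = 1 − x + f·(3x − 1)

and eliminating f from HOM + HET + NULL = 1 gives the cubic in x

    x³ + (1 + HOM)·x² + (3·HET + 2·HOM − 3)·x + NULL = 0

whose root in [0, √2 − 1) is the undercall-rate estimate.  From it,
f = HET/(1 − 2x − x²), the count of heterozygous sites not reported
heterozygous is missing = (f − HET)·N, and the count reported homozygous is
het2hom = missing − N·NULL·HET/(HET + HOM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeTable

#: Upper end of the undercall-rate domain: 1 - 2x - x^2 > 0 requires x < sqrt(2) - 1.
X_MAX = math.sqrt(2.0) - 1.0

_ACGT = frozenset("ACGT")


class EstimationError(RuntimeError):
    """No admissible undercall-rate solution exists for the given proportions."""


@dataclass(frozen=True)
class CallClassCounts:
    """Observed HOM/HET/NULL counts among the N eligible markers of one individual."""

    N: int
    n_hom: int
    n_het: int
    n_null: int

    def __post_init__(self):
        if self.n_hom + self.n_het + self.n_null != self.N:
            raise ValueError("call-class counts must sum to N")

    @property
    def HOM(self) -> float:
        return self.n_hom / self.N

    @property
    def HET(self) -> float:
        return self.n_het / self.N

    @property
    def NULL(self) -> float:
        return self.n_null / self.N


@dataclass(frozen=True)
class UndercallEstimate:
    """Fitted undercall model: rate ``x``, true heterozygous fraction ``f``,
    expected count of heterozygous sites not reported heterozygous
    (``missing``) and of those reported homozygous (``het2hom``)."""

    x: float
    f: float
    missing: float
    het2hom: float
    counts: CallClassCounts

    @property
    def missing_count(self) -> int:
        return _round_half_up(self.missing)

    @property
    def het2hom_count(self) -> int:
        return _round_half_up(self.het2hom)


def _round_half_up(v: float) -> int:
    return math.floor(v + 0.5)


def classify_calls(table: GenotypeTable, *, rs_only: bool = True,
                   acgt_only: bool = True) -> CallClassCounts:
    """Count HOM / HET / NULL calls among eligible markers.

    Eligible markers carry a dbSNP ``rs`` identifier and a genotype that is
    either ``--`` or two alleles from {A,C,G,T}; vendor-internal ``i…``
    markers, indel (I/D) genotypes and haploid calls are excluded from N.
    The flags relax the identifier and alphabet filters for sensitivity
    analysis.
    """
    df = table.df
    g = df["genotype"]
    eligible = np.ones(len(df), dtype=bool)
    if rs_only:
        eligible &= df["marker_id"].str.startswith("rs").to_numpy()
    is_null = (g == "--").to_numpy()
    diploid = (g.str.len() == 2).to_numpy() & ~is_null
    if acgt_only:
        diploid &= g.str.fullmatch("[ACGT]{2}").fillna(False).to_numpy()
    eligible &= is_null | diploid
    if not eligible.any():
        raise ValueError("no eligible markers to classify")
    gg = g.to_numpy()[eligible]
    null = gg == "--"
    first = np.array([s[0] for s in gg])
    second = np.array([s[-1] for s in gg])
    het = ~null & (first != second)
    hom = ~null & ~het
    return CallClassCounts(N=int(eligible.sum()), n_hom=int(hom.sum()),
                           n_het=int(het.sum()), n_null=int(null.sum()))


def expected_call_frequencies(f: float, x: float) -> tuple[float, float, float]:
    """Forward model: expected (NULL', HET', HOM') observed-class frequencies."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"heterozygous fraction f={f} outside [0, 1]")
    if not 0.0 <= x < X_MAX:
        raise ValueError(f"undercall rate x={x} outside [0, {X_MAX:.6f})")
    null = f * x * x + (1.0 - f) * x
    het = f * (1.0 - 2.0 * x - x * x)
    hom = 1.0 - x + f * (3.0 * x - 1.0)
    return null, het, hom


def solve_undercall_rate(HOM: float, HET: float, NULL: float) -> float:
    """Solve the undercall cubic for x given observed class proportions.

    Real roots are filtered to [0, √2 − 1); among admissible roots the one
    whose forward frequencies (with f = HET/(1 − 2x − x²)) best reproduce the
    inputs is returned, ties broken toward the smallest x.  Raises
    :class:`EstimationError` if no admissible root exists.
    """
    for name, v in (("HOM", HOM), ("HET", HET), ("NULL", NULL)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if abs(HOM + HET + NULL - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    roots = np.roots([1.0, 1.0 + HOM, 3.0 * HET + 2.0 * HOM - 3.0, NULL])
    real = roots[np.abs(roots.imag) < 1e-9].real
    real[np.abs(real) < 1e-12] = 0.0
    candidates = sorted(x for x in real if 0.0 <= x < X_MAX)
    if not candidates:
        raise EstimationError(
            f"no undercall-rate root in [0, {X_MAX:.6f}) for "
            f"HOM={HOM}, HET={HET}, NULL={NULL}")
    if len(candidates) == 1:
        return float(candidates[0])

    def residual(x: float) -> float:
        denom = 1.0 - 2.0 * x - x * x
        f = HET / denom if denom > 0 else np.inf
        if not 0.0 <= f <= 1.0:
            return np.inf
        en, eh, eo = expected_call_frequencies(f, x)
        return abs(en - NULL) + abs(eh - HET) + abs(eo - HOM)

    return float(min(candidates, key=lambda x: (residual(x), x)))


def estimate_undercall(counts: CallClassCounts) -> UndercallEstimate:
    """Full estimate: x, f, missing and het2hom from observed call-class counts."""
    HOM, HET, NULL = counts.HOM, counts.HET, counts.NULL
    if HET == 0.0 and NULL > 0.0:
        warnings.warn("HET = 0: heterozygous fraction f is unidentifiable; "
                      "returning the homozygous-only solution x = NULL")
        x = NULL
    else:
        x = solve_undercall_rate(HOM, HET, NULL)
    f = HET / (1.0 - 2.0 * x - x * x)
    missing = (f - HET) * counts.N
    if HET + HOM > 0:
        het2hom = missing - counts.N * NULL * HET / (HET + HOM)
    else:
        het2hom = 0.0
    return UndercallEstimate(x=x, f=f, missing=missing, het2hom=het2hom, counts=counts)
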