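"""Duplex population model for denature/re-hybridize mixing experiments.

A mix containing mutant fraction ``p`` that is melted and re-annealed
under random strand pairing yields homoduplexes and heteroduplexes in
Hardy-Weinberg-like proportions: ``(1-p)^2 : p^2 : 2p(1-p)``.  The
heteroduplex fraction peaks at 50% when ``p = 0.5``, which is why mixing
equal quantities of WT and mutant DNA maximizes EMC assay signal.

The two heteroduplex strand orientations (WT sense / mutant antisense
and mutant sense / WT antisense) are formed in equal amounts and are
tracked separately downstream because their cleavage products differ in
apparent size around a bulge.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MixSpec",
    "DuplexPopulation",
    "reanneal",
    "pool_allele_fraction",
    "hetero_yield_per_mutant_strand",
]


@dataclass(frozen=True)
class MixSpec:
    """A WT + mutant amplicon mix prior to heteroduplex formation.

    ``p_mut`` is the mutant molar fraction; ``total_mass`` the amount of
    dsDNA in ng (the assay default is 250 ng of pooled PCR product).
    """

    p_mut: float
    total_mass: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mut <= 1.0:
            raise ValueError(f"p_mut must lie in [0, 1], got {self.p_mut}")
        if self.total_mass <= 0:
            raise ValueError("total_mass must be positive")


@dataclass(frozen=True)
class DuplexPopulation:
    """Molar duplex fractions after random re-annealing."""

    f_wt_homo: float
    f_mut_homo: float
    f_hetero: float

    @property
    def f_hetero_per_orientation(self) -> float:
        """Each of the two strand orientations carries half the heteroduplex."""
        return self.f_hetero / 2.0


def reanneal(mix: MixSpec) -> DuplexPopulation:
    """Random re-annealing of complementary strands at equilibrium.

    No kinetic bias between homo- and heteroduplex formation is modelled,
    so a sense strand pairs with a WT antisense strand with probability
    ``1-p`` and a mutant antisense strand with probability ``p``.
    """
    p = mix.p_mut
    return DuplexPopulation(
        f_wt_homo=(1.0 - p) ** 2,
        f_mut_homo=p**2,
        f_hetero=2.0 * p * (1.0 - p),
    )


def pool_allele_fraction(n_individuals: int, n_het_mutants: int, ploidy: int = 2) -> float:
    """Mutant allele fraction when pooling individuals before the assay.

    One heterozygote in a pool of eight diploids contributes 1 of 16
    alleles, i.e. 6.25% mutant DNA.
    """
    if n_individuals < 1:
        raise ValueError("pool must contain at least one individual")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0 <= n_het_mutants <= n_individuals:
        raise ValueError("n_het_mutants must lie in [0, n_individuals]")
    return n_het_mutants / (n_individuals * ploidy)


def hetero_yield_per_mutant_strand(p: float) -> float:
    """Fraction of mutant strands that end up in heteroduplexes, ``1 - p``.

    Distinct from the heteroduplex fraction of total DNA: as a mutant is
    diluted into a larger pool (p -> 0) nearly every mutant strand finds
    a WT partner even though heteroduplexes become a small share of the
    total duplex population.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return 1.0 - p
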