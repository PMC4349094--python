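"""Enzyme cleavage model: lesion sites -> strand-resolved digestion fragments.

Mismatch-specific endonucleases (T7 endonuclease I, Surveyor/CELII) nick
heteroduplex DNA on the 3' side of a lesion; within one reaction the
opposite strand is assumed to receive a counter-nick at the same site,
so every cleavage event yields a double-strand break and the assay reads
out dsDNA fragments.  Cleavage events at distinct sites are independent
Bernoulli trials, which produces the characteristic partial-digest peak
ladder when several lesions share one amplicon.

Cut placement convention: a cut at WT coordinate ``i`` severs the strand
immediately 3' of base ``i``, so the 5' fragment has length ``i``.  For
a bulge the cut lands 3' of the bulge *on the bulge-carrying strand*;
because the 3' direction reverses between the two heteroduplex strand
orientations, a k-nt deletion heteroduplex yields flanking products that
differ by exactly k bp between orientations (the doublet seen on the
electropherogram).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alleles import MismatchMap, MismatchSite
from .reanneal import DuplexPopulation

__all__ = [
    "EnzymeProfile",
    "NoisePreset",
    "CleavageSite",
    "DuplexFragment",
    "DigestState",
    "DigestResult",
    "cleavage_sites",
    "full_digest",
    "partial_digest",
    "duplex_product_sizes",
    "heteroduplex_digests",
    "population_fragments",
    "bulge_class",
    "load_profile",
    "ORIENTATIONS",
]

#: The two heteroduplex strand orientations: which allele contributes the
#: sense strand of the duplex.
ORIENTATIONS = ("wt_sense", "mut_sense")

MAX_SITES = 16

BULGE_CLASSES = ("1", "2-19", "20+")


def bulge_class(size: int) -> str:
    """Size class of an extrahelical bulge: 1 nt, 2-19 nt, or >= 20 nt."""
    if size < 1:
        raise ValueError("bulge size must be >= 1")
    if size == 1:
        return "1"
    if size <= 19:
        return "2-19"
    return "20+"


@dataclass(frozen=True)
class NoisePreset:
    """Electropherogram noise attached to an enzyme preset.

    ``exo_background_mass`` is the fraction of fragment mass that the
    enzyme's nonspecific exonuclease activity converts into sub-25-bp
    degradation products, rendered as an exponentially decaying spectrum
    with scale ``exo_background_decay_nt``.
    """

    baseline_fu: float = 0.0
    baseline_jitter_fu: float = 0.0
    exo_background_mass: float = 0.0
    exo_background_decay_nt: float = 8.0


@dataclass(frozen=True)
class EnzymeProfile:
    """Per-lesion cleavage probabilities and exonuclease parameters.

    ``p_cut_snv`` applies to single-base mismatches; ``p_cut_bulge`` maps
    bulge size classes ("1", "2-19", "20+") to cleavage probabilities.
    ``exo_nibbling_rate`` is the mean number of nucleotides removed per
    5' end (Surveyor > 0, T7E1 = 0).  Homoduplexes are not cleaved.
    """

    name: str
    p_cut_snv: float
    p_cut_bulge: Mapping[str, float]
    cut_side: str = "3prime"
    exo_nibbling_rate: float = 0.0
    background_small_fragment_mass: float = 0.0
    noise: NoisePreset = field(default_factory=NoisePreset)

    def __post_init__(self) -> None:
        probs = [self.p_cut_snv, *self.p_cut_bulge.values()]
        if any(not 0.0 <= q <= 1.0 for q in probs):
            raise ValueError("cleavage probabilities must lie in [0, 1]")
        if set(self.p_cut_bulge) != set(BULGE_CLASSES):
            raise ValueError(f"p_cut_bulge must have keys {BULGE_CLASSES}")
        if self.exo_nibbling_rate < 0 or self.background_small_fragment_mass < 0:
            raise ValueError("exonuclease parameters must be >= 0")
        if self.cut_side != "3prime":
            raise ValueError("only 3' cleavage is modelled")

    def p_cut(self, site: MismatchSite) -> float:
        if site.kind == "SNV":
            return self.p_cut_snv
        return self.p_cut_bulge[bulge_class(site.bulge_size)]

    @classmethod
    def from_dict(cls, doc: Mapping) -> "EnzymeProfile":
        enz = doc["enzyme"]
        noise = NoisePreset(**doc.get("noise", {}))
        return cls(
            name=doc["name"],
            p_cut_snv=enz["p_cut_snv"],
            p_cut_bulge=dict(enz["p_cut_bulge"]),
            cut_side=enz.get("cut_side", "3prime"),
            exo_nibbling_rate=enz.get("exo_nibbling_rate", 0.0),
            background_small_fragment_mass=enz.get("background_small_fragment_mass", 0.0),
            noise=noise,
        )


def load_profile(source: str | Path) -> EnzymeProfile:
    """Load an enzyme profile from a packaged preset name or a JSON path.

    Packaged presets: ``"t7e1"`` and ``"surveyor"``.
    """
    name = str(source).lower()
    if name in ("t7e1", "surveyor"):
        text = resources.files("emcsim.data").joinpath(f"{name}.json").read_text()
    else:
        text = Path(source).read_text()
    return EnzymeProfile.from_dict(json.loads(text))


@dataclass(frozen=True)
class CleavageSite:
    position: int
    p_cut: float
    lesion_kind: str
    bulge_size: int = 0
    bulge_strand: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cut <= 1.0:
            raise ValueError("p_cut must lie in [0, 1]")


def cleavage_sites(m: MismatchMap, e: EnzymeProfile) -> list[CleavageSite]:
    """One cleavage site per lesion, probabilities from the enzyme profile."""
    return [
        CleavageSite(s.position, e.p_cut(s), s.kind, s.bulge_size, s.bulge_strand)
        for s in m
    ]


def _mut_offset_before(sites: Sequence[CleavageSite], wt_cut: int, exclude: int | None) -> int:
    """Cumulative mutant-coordinate offset from bulges left of a WT cut."""
    off = 0
    for j, s in enumerate(sites):
        if j == exclude or s.lesion_kind != "bulge":
            continue
        if s.bulge_strand == "wt":  # deletion: mutant lacks these bases
            if s.position + s.bulge_size - 1 <= wt_cut:
                off -= s.bulge_size
        else:  # insertion before WT base s.position
            if s.position <= wt_cut:
                off += s.bulge_size
    return off


def _cut_pair(sites: Sequence[CleavageSite], i: int, orientation: str) -> tuple[int, int]:
    """(WT-strand cut, mutant-strand cut) for site *i* in one orientation.

    Coordinates count bases 5'->3' on each strand's own sequence; a cut
    value c means the break falls immediately after base c.
    """
    s = sites[i]
    if s.lesion_kind == "SNV":
        wt_cut = s.position
        return wt_cut, wt_cut + _mut_offset_before(sites, wt_cut, None)
    d, k = s.position, s.bulge_size
    junction_mut = (d - 1) + _mut_offset_before(sites, d - 1, i)
    if s.bulge_strand == "wt":
        # bulge on the WT strand; 3' of the bulge is the high-coordinate
        # side when WT is the sense strand, the low side otherwise
        wt_cut = d + k - 1 if orientation == "wt_sense" else d - 1
        return wt_cut, junction_mut
    # bulge on the mutant strand (insertion before WT base d)
    mut_cut = junction_mut + (k if orientation == "mut_sense" else 0)
    return d - 1, mut_cut


def _fragments_from_cuts(cuts: Iterable[int], length: int) -> tuple[int, ...]:
    bounds = sorted({0, length, *cuts})
    if bounds[0] < 0 or bounds[-1] > length:
        raise ValueError("cut coordinate outside the strand")
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass(frozen=True)
class DuplexFragment:
    """One double-stranded digestion product."""

    wt_strand: int
    mut_strand: int

    @property
    def apparent_size(self) -> int:
        """Longer-strand length: a 3' overhang adds to apparent size."""
        return max(self.wt_strand, self.mut_strand)


@dataclass(frozen=True)
class DigestState:
    cut_sites: tuple[int, ...]  # indices into the site list
    probability: float
    fragments: tuple[DuplexFragment, ...]


@dataclass(frozen=True)
class DigestResult:
    """All 2^k partial-digestion states of one duplex species."""

    states: tuple[DigestState, ...]
    orientation: str
    wt_len: int
    mut_len: int

    def fragment_abundances(self) -> dict[DuplexFragment, float]:
        """Probability-weighted molar abundance of each distinct product."""
        acc: dict[DuplexFragment, float] = {}
        for st in self.states:
            for fr in st.fragments:
                acc[fr] = acc.get(fr, 0.0) + st.probability
        return acc

    def sized_abundances(self) -> dict[int, float]:
        """Molar abundance keyed by apparent (longer-strand) size."""
        acc: dict[int, float] = {}
        for fr, ab in self.fragment_abundances().items():
            acc[fr.apparent_size] = acc.get(fr.apparent_size, 0.0) + ab
        return acc


def _validate_sites(sites: Sequence[CleavageSite], wt_len: int) -> None:
    pos = [s.position for s in sites]
    if len(set(pos)) != len(pos):
        raise ValueError("duplicate cleavage site positions")
    if any(p >= wt_len or p < 1 for p in pos):
        raise ValueError("cleavage site positions must lie inside the amplicon")


def full_digest(
    sites: Sequence[CleavageSite],
    wt_len: int,
    mut_len: int,
    orientation: str = "wt_sense",
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Fragment lengths of each strand when every site is cleaved.

    Returns ``(wt_strand_fragments, mut_strand_fragments)`` in 5'->3'
    order of the WT sense coordinate.
    """
    _validate_sites(sites, wt_len)
    pairs = [_cut_pair(sites, i, orientation) for i in range(len(sites))]
    wt_fr = _fragments_from_cuts([c for c, _ in pairs], wt_len)
    mut_fr = _fragments_from_cuts([c for _, c in pairs], mut_len)
    return wt_fr, mut_fr


def partial_digest(
    sites: Sequence[CleavageSite],
    wt_len: int,
    mut_len: int,
    orientation: str = "wt_sense",
) -> DigestResult:
    """Enumerate all cut subsets with independent per-site probabilities.

    Each of the 2^k states pairs the i-th WT-strand fragment with the
    i-th mutant-strand fragment (both strands are cut at the same sites,
    so fragment counts match).  State probabilities sum to 1.
    """
    _validate_sites(sites, wt_len)
    k = len(sites)
    if k > MAX_SITES:
        raise ValueError(
            f"{k} sites exceed the 2^{MAX_SITES} enumeration cap; "
            "merge nearby lesions or cap the site list"
        )
    pairs = [_cut_pair(sites, i, orientation) for i in range(k)]
    states = []
    for subset in itertools.product((False, True), repeat=k):
        prob = 1.0
        for cut, s in zip(subset, sites):
            prob *= s.p_cut if cut else 1.0 - s.p_cut
        chosen = tuple(i for i, c in enumerate(subset) if c)
        wt_fr = _fragments_from_cuts([pairs[i][0] for i in chosen], wt_len)
        mut_fr = _fragments_from_cuts([pairs[i][1] for i in chosen], mut_len)
        frs = tuple(DuplexFragment(w, m) for w, m in zip(wt_fr, mut_fr))
        states.append(DigestState(chosen, prob, frs))
    return DigestResult(tuple(states), orientation, wt_len, mut_len)


def heteroduplex_digests(
    m: MismatchMap,
    enzyme: EnzymeProfile,
    wt_len: int,
    mut_len: int,
) -> dict[str, DigestResult]:
    """Partial digests of both heteroduplex strand orientations."""
    sites = cleavage_sites(m, enzyme)
    return {o: partial_digest(sites, wt_len, mut_len, o) for o in ORIENTATIONS}


def duplex_product_sizes(
    digests: DigestResult | Mapping[str, DigestResult],
    weights: Mapping[str, float] | None = None,
) -> dict[int, float]:
    """Apparent-size multiset over one or both heteroduplex orientations.

    With both orientations (default equal weights) a deletion
    heteroduplex cut at the bulge contributes flanking products whose
    sizes differ by exactly the bulge size between orientations.
    """
    if isinstance(digests, DigestResult):
        digests = {digests.orientation: digests}
    if weights is None:
        w = 1.0 / len(digests)
        weights = {o: w for o in digests}
    acc: dict[int, float] = {}
    for o, d in digests.items():
        for size, ab in d.sized_abundances().items():
            acc[size] = acc.get(size, 0.0) + weights[o] * ab
    return dict(sorted(acc.items()))


def population_fragments(
    pop: DuplexPopulation,
    m: MismatchMap,
    enzyme: EnzymeProfile,
    wt_len: int,
    mut_len: int,
) -> dict[int, float]:
    """Apparent-size fragment abundances of a full re-annealed mix.

    Homoduplexes stay intact (the enzyme model does not cleave perfectly
    paired DNA); each heteroduplex orientation carries half of
    ``f_hetero`` and is digested independently.
    """
    acc: dict[int, float] = {}

    def add(size: int, ab: float) -> None:
        if ab > 0.0:
            acc[size] = acc.get(size, 0.0) + ab

    add(wt_len, pop.f_wt_homo)
    add(mut_len, pop.f_mut_homo)
    if pop.f_hetero > 0.0:
        half = pop.f_hetero_per_orientation
        for d in heteroduplex_digests(m, enzyme, wt_len, mut_len).values():
            for size, ab in d.sized_abundances().items():
                add(size, half * ab)
    return dict(sorted(acc.items()))
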