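"""Amplicons, variant edit lists, and heteroduplex mismatch maps.

An enzyme-mismatch-cleavage (EMC) assay reads out the lesions of a
WT/mutant heteroduplex: single-base mismatches (SNVs) and extrahelical
bulges created by insertions or deletions.  This module represents the
wild-type amplicon, the explicit edits that define a mutant allele, and
the derived per-lesion map in wild-type coordinates.

Coordinate convention: positions are 1-based on the wild-type amplicon,
and a lesion's position is the first affected wild-type base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Amplicon",
    "Edit",
    "VariantSpec",
    "MismatchSite",
    "MismatchMap",
    "apply_variants",
    "map_mismatches",
]

_BASES = frozenset("ACGT")

EDIT_KINDS = ("substitution", "deletion", "insertion")


@dataclass(frozen=True)
class Amplicon:
    """A double-stranded PCR product, stored as its sense strand."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _BASES
        if bad:
            raise ValueError(f"amplicon {self.name!r}: non-ACGT characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        """G+C fraction of the sense strand."""
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0


@dataclass(frozen=True)
class Edit:
    """One edit on the wild-type amplicon.

    ``pos`` is the 1-based coordinate of the first affected WT base.  For a
    substitution ``ref``/``alt`` have equal length; for a deletion ``alt``
    is empty and ``ref`` holds the deleted bases; for an insertion ``ref``
    is empty and the inserted bases go *before* WT base ``pos``.
    """

    pos: int
    kind: str
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.pos < 1:
            raise ValueError(f"edit position must be >= 1, got {self.pos}")
        if self.kind == "substitution":
            if not self.ref or len(self.ref) != len(self.alt):
                raise ValueError(f"substitution at {self.pos}: ref/alt lengths differ")
        elif self.kind == "deletion":
            if not self.ref or self.alt:
                raise ValueError(f"deletion at {self.pos}: needs non-empty ref, empty alt")
        else:  # insertion
            if self.ref or not self.alt:
                raise ValueError(f"insertion at {self.pos}: needs empty ref, non-empty alt")

    @property
    def ref_span(self) -> int:
        """Number of WT bases consumed by this edit."""
        return len(self.ref)


@dataclass(frozen=True)
class VariantSpec:
    """An ordered, non-overlapping list of edits defining a mutant allele."""

    edits: tuple[Edit, ...]

    def __init__(self, edits: Iterable[Edit]) -> None:
        object.__setattr__(self, "edits", tuple(edits))

    def __len__(self) -> int:
        return len(self.edits)

    def validate(self, wt: Amplicon) -> None:
        """Check ordering, bounds, overlap and ref agreement against *wt*.

        Raises ``ValueError`` with the offending position on failure.
        """
        prev_end = 0  # last WT coordinate consumed so far
        for e in self.edits:
            if e.pos <= prev_end:
                raise ValueError(f"edits out of order or overlapping at position {e.pos}")
            end = e.pos + max(e.ref_span, 1) - 1
            if end > wt.length:
                raise ValueError(f"edit at position {e.pos} runs past amplicon end ({wt.length} bp)")
            if e.ref:
                observed = wt.sequence[e.pos - 1 : e.pos - 1 + e.ref_span]
                if observed != e.ref:
                    raise ValueError(
                        f"ref mismatch at position {e.pos}: expected {e.ref!r}, amplicon has {observed!r}"
                    )
            prev_end = e.pos + e.ref_span - 1 if e.ref else e.pos - 1
        # positions strictly increasing is implied by the overlap check above


@dataclass(frozen=True)
class MismatchSite:
    """One heteroduplex lesion in WT coordinates."""

    position: int
    kind: str  # "SNV" | "bulge"
    bulge_size: int = 0
    bulge_strand: str = "none"  # "wt" | "mutant" | "none"

    def __post_init__(self) -> None:
        if self.kind == "SNV":
            if self.bulge_size != 0 or self.bulge_strand != "none":
                raise ValueError("SNV sites carry no bulge")
        elif self.kind == "bulge":
            if self.bulge_size < 1 or self.bulge_strand not in ("wt", "mutant"):
                raise ValueError("bulge sites need bulge_size >= 1 and a strand")
        else:
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class MismatchMap:
    """Ordered lesion sites of a WT/mutant heteroduplex."""

    sites: tuple[MismatchSite, ...]

    def __init__(self, sites: Iterable[MismatchSite]) -> None:
        sites = tuple(sites)
        pos = [s.position for s in sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("mismatch sites must have strictly increasing positions")
        object.__setattr__(self, "sites", sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def apply_variants(wt: Amplicon, v: VariantSpec, name: str | None = None) -> Amplicon:
    """Realize the mutant allele sequence by applying *v* to *wt*.

    Substitutions leave the length unchanged; the returned length is
    ``wt.length - deleted + inserted``.
    """
    v.validate(wt)
    seq = wt.sequence
    parts: list[str] = []
    cursor = 0  # 0-based index into WT of the next unconsumed base
    for e in v.edits:
        start = e.pos - 1
        if e.kind == "insertion":
            parts.append(seq[cursor:start])
            parts.append(e.alt)
            cursor = start
        else:
            parts.append(seq[cursor:start])
            parts.append(e.alt)  # "" for deletion
            cursor = start + e.ref_span
    parts.append(seq[cursor:])
    return Amplicon(name or f"{wt.name}_mut", "".join(parts))


def map_mismatches(wt: Amplicon, v: VariantSpec) -> MismatchMap:
    """Derive the heteroduplex lesion map, one site per edit position.

    A multi-base substitution becomes a run of SNV sites, one per
    mismatched base; a k-nt deletion becomes a k-nt bulge on the WT
    strand; a k-nt insertion a k-nt bulge on the mutant strand.
    """
    v.validate(wt)
    sites: list[MismatchSite] = []
    for e in v.edits:
        if e.kind == "substitution":
            for i, (r, a) in enumerate(zip(e.ref, e.alt)):
                if r != a:
                    sites.append(MismatchSite(e.pos + i, "SNV"))
        elif e.kind == "deletion":
            sites.append(MismatchSite(e.pos, "bulge", len(e.ref), "wt"))
        else:
            sites.append(MismatchSite(e.pos, "bulge", len(e.alt), "mutant"))
    return MismatchMap(sites)
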