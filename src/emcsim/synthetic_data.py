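"""Surrogate fixtures: amplicons, designed deletions, complex alleles.

The assay's behaviour in this model depends on amplicon length, GC
content, and lesion positions/classes — not on sequence identity — so
every experiment can run on surrogate amplicons generated to the
documented lengths and GC contents (exon 2a: 488 bp / 35.0% GC, exon 3:
572 bp / 37.6%, exon 6: 500 bp / 37.4%).  Sequences are random with
exact base counts; the wild-type bases at the complex-allele
substitution positions are forced to the documented reference alleles so
the documented transitions (A>G, T>A, T>C) are representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alleles import Amplicon, Edit, VariantSpec

__all__ = [
    "AmpliconPreset",
    "AMPLICON_PRESETS",
    "COMPLEX_ALLELES",
    "generate_amplicon",
    "design_deletion",
    "make_complex_allele",
    "write_fixtures",
    "FIXTURE_SEED",
]

#: Seed under which the packaged fixtures are generated.
FIXTURE_SEED = 20130915


@dataclass(frozen=True)
class AmpliconPreset:
    name: str
    length: int
    gc: float


AMPLICON_PRESETS = {
    "exon2a": AmpliconPreset("exon2a", 488, 0.350),
    "exon3": AmpliconPreset("exon3", 572, 0.376),
    "exon6": AmpliconPreset("exon6", 500, 0.374),
}

#: WT reference bases required at substitution positions of the complex
#: alleles (1-based, exon 2a surrogate).
_FORCED_BASES = {85: "A", 89: "A", 293: "T", 78: "T", 127: "T", 347: "T"}

#: Complex allele templates recovered from engineered-nuclease embryos:
#: a shared 1-nt deletion at 46 plus three substitutions each.
COMPLEX_ALLELES = {
    "D15": (
        ("deletion", 46, 1, None),
        ("substitution", 85, "A", "G"),
        ("substitution", 89, "A", "G"),
        ("substitution", 293, "T", "A"),
    ),
    "D19": (
        ("deletion", 46, 1, None),
        ("substitution", 78, "T", "C"),
        ("substitution", 127, "T", "C"),
        ("substitution", 347, "T", "C"),
    ),
}


def generate_amplicon(preset: AmpliconPreset | str, seed: int = FIXTURE_SEED) -> Amplicon:
    """Random surrogate amplicon with exact length and near-exact GC.

    Base counts are fixed by rounding (GC within 0.5 points of the
    preset by construction), the sequence is shuffled deterministically,
    and the forced reference bases are installed by swapping (which
    preserves base counts exactly).
    """
    if isinstance(preset, str):
        preset = AMPLICON_PRESETS[preset]
    rng = np.random.default_rng(seed)
    n = preset.length
    n_gc = round(preset.gc * n)
    counts = {
        "G": n_gc // 2,
        "C": n_gc - n_gc // 2,
        "A": (n - n_gc) // 2,
        "T": (n - n_gc) - (n - n_gc) // 2,
    }
    bases = np.array(list("".join(b * c for b, c in counts.items())))
    rng.shuffle(bases)
    forced = {p: b for p, b in _FORCED_BASES.items() if p <= n}
    for pos, base in forced.items():
        i = pos - 1
        if bases[i] == base:
            continue
        donors = np.flatnonzero(bases == base)
        donors = [j for j in donors if (j + 1) not in forced]
        if not donors:
            raise ValueError(f"no donor base {base!r} available for position {pos}")
        j = donors[int(rng.integers(len(donors)))]
        bases[i], bases[j] = bases[j], bases[i]
    return Amplicon(preset.name, "".join(bases))


def design_deletion(
    amplicon: Amplicon,
    del_size: int = 20,
    product_diff_bp: tuple[int, int] = (150, 200),
    start: int | None = None,
) -> VariantSpec:
    """Place a deletion so the two cleavage products differ by 150-200 bp.

    A cut at the deletion junction of the heteroduplex splits the mutant
    strand (length L - k) into pieces of ``start - 1`` and
    ``L - k - start + 1`` bp; their difference must land in
    ``product_diff_bp``.  By default the midpoint of the feasible start
    window is used; an explicit ``start`` outside the window is
    rejected.
    """
    L, k = amplicon.length, del_size
    lo_diff, hi_diff = product_diff_bp
    # difference = (L - k) - 2*(start - 1) for the short side on the left
    lo_start = (L - k + 2 - hi_diff + 1) // 2
    hi_start = (L - k + 2 - lo_diff) // 2
    lo_start = max(lo_start, 2)
    hi_start = min(hi_start, L - k)
    if lo_start > hi_start:
        raise ValueError(
            f"no feasible {del_size}-bp deletion placement on a {L}-bp amplicon "
            f"for a {lo_diff}-{hi_diff} bp product-size difference"
        )
    if start is None:
        start = (lo_start + hi_start) // 2
    diff = abs((L - k) - 2 * (start - 1))
    if not lo_diff <= diff <= hi_diff:
        raise ValueError(
            f"deletion start {start} gives a product-size difference of {diff} bp, "
            f"outside [{lo_diff}, {hi_diff}]"
        )
    ref = amplicon.sequence[start - 1 : start - 1 + k]
    return VariantSpec([Edit(start, "deletion", ref=ref)])


def make_complex_allele(amplicon: Amplicon, template: str) -> VariantSpec:
    """Edit list for one of the documented complex alleles (D15 / D19)."""
    if template not in COMPLEX_ALLELES:
        raise ValueError(f"unknown complex allele template {template!r}")
    if amplicon.length < 488:
        raise ValueError("complex alleles need an amplicon of at least 488 bp")
    edits = []
    for kind, pos, ref, alt in COMPLEX_ALLELES[template]:
        if kind == "deletion":
            edits.append(Edit(pos, "deletion", ref=amplicon.sequence[pos - 1 : pos - 1 + ref]))
        else:
            edits.append(Edit(pos, "substitution", ref=ref, alt=alt))
    return VariantSpec(sorted(edits, key=lambda e: e.pos))


def write_fixtures(outdir: str | Path, seed: int = FIXTURE_SEED) -> dict:
    """Write FASTA amplicons, JSON variant specs, and a seed manifest."""
    from . import io as emc_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    amplicons = {name: generate_amplicon(name, seed) for name in AMPLICON_PRESETS}
    emc_io.write_fasta(outdir / "amplicons.fasta", amplicons.values())

    manifest: dict = {"seed": seed, "amplicons": {}, "variants": {}}
    for name, amp in amplicons.items():
        manifest["amplicons"][name] = {"length": amp.length, "gc": round(amp.gc, 4)}
        v = design_deletion(amp)
        path = outdir / f"{name}_del20.json"
        emc_io.write_variant_spec(path, v)
        manifest["variants"][f"{name}_del20"] = {
            "file": path.name,
            "start": v.edits[0].pos,
        }
    for template in COMPLEX_ALLELES:
        v = make_complex_allele(amplicons["exon2a"], template)
        path = outdir / f"exon2a_{template}.json"
        emc_io.write_variant_spec(path, v)
        manifest["variants"][f"exon2a_{template}"] = {"file": path.name}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
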