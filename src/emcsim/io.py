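"""File formats: FASTA amplicons, JSON variant specs, CSV traces, TSV tables.

Trace CSV dialect: comma-separated, UTF-8, '.' decimal, header
``apparent_size_bp,fluorescence_fu`` — chip-software exports vary by
locale, so the dialect is fixed here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import Amplicon, Edit, VariantSpec
from .trace_sim import Trace

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variant_spec",
    "write_variant_spec",
    "read_trace_csv",
    "write_trace_csv",
]

TRACE_COLUMNS = ("apparent_size_bp", "fluorescence_fu")


def read_fasta(path: str | Path) -> dict[str, Amplicon]:
    """Read amplicons from (multi-record) FASTA; record id = name."""
    amps = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        amps[rec.id] = Amplicon(rec.id, str(rec.seq))
    if not amps:
        raise ValueError(f"no FASTA records in {path}")
    return amps


def write_fasta(path: str | Path, amplicons: Iterable[Amplicon]) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description=f"{a.length} bp GC={a.gc:.3f}")
        for a in amplicons
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variant_spec(path: str | Path) -> VariantSpec:
    doc = json.loads(Path(path).read_text())
    edits = doc["edits"] if isinstance(doc, dict) else doc
    return VariantSpec(
        Edit(e["pos"], e["kind"], e.get("ref", ""), e.get("alt", "")) for e in edits
    )


def write_variant_spec(path: str | Path, v: VariantSpec) -> None:
    doc = {
        "edits": [
            {"pos": e.pos, "kind": e.kind, "ref": e.ref, "alt": e.alt} for e in v.edits
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_trace_csv(path: str | Path, trace: Trace) -> None:
    df = pd.DataFrame({TRACE_COLUMNS[0]: trace.axis, TRACE_COLUMNS[1]: trace.signal})
    df.to_csv(path, index=False, float_format="%.6g")


def read_trace_csv(path: str | Path) -> Trace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} lacks columns {missing}")
    return Trace(
        axis=df[TRACE_COLUMNS[0]].to_numpy(float),
        signal=df[TRACE_COLUMNS[1]].to_numpy(float),
    )
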