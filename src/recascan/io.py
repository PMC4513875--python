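"""FASTA input and tabular output helpers.

Aligned pairs arrive as plain FASTA with records paired either in file
order (1st with 2nd, 3rd with 4th, ...) or by shared IDs carrying /1 and
/2 suffixes.  Parsing is delegated to Biopython's SeqIO.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .fret import FluorescenceTrace
from .patterns import AlignedPair, AlignmentError

__all__ = [
    "read_aligned_pairs_fasta",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_manifest",
]


def read_aligned_pairs_fasta(path: str | Path) -> list[AlignedPair]:
    """Read aligned sequence pairs from a FASTA file.

    If every record ID ends in ``/1`` or ``/2`` the pairs are joined by
    the shared stem; otherwise consecutive records are paired in order
    and the pair takes the first record's ID as its name.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if all(i.endswith(("/1", "/2")) for i in ids):
        by_stem: dict[str, dict[str, str]] = {}
        for rec in records:
            stem, mate = rec.id[:-2], rec.id[-1]
            by_stem.setdefault(stem, {})[mate] = str(rec.seq)
        pairs = []
        for stem, mates in by_stem.items():
            if set(mates) != {"1", "2"}:
                raise AlignmentError(f"record {stem!r} lacks a /1+/2 mate pair")
            pairs.append(AlignedPair(name=stem, seq_a=mates["1"], seq_b=mates["2"]))
        return pairs
    if len(records) % 2:
        raise AlignmentError(
            f"{path}: odd record count {len(records)} cannot be paired in order"
        )
    return [
        AlignedPair(name=a.id, seq_a=str(a.seq), seq_b=str(b.seq))
        for a, b in zip(records[::2], records[1::2])
    ]


def write_trace_tsv(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write one trace as two-column TSV (time_s, emission_au)."""
    pd.DataFrame({"time_s": trace.times, "emission_au": trace.emission}).to_csv(
        path, sep="\t", index=False
    )


def read_trace_tsv(path: str | Path, name: str | None = None) -> FluorescenceTrace:
    df = pd.read_csv(path, sep="\t")
    return FluorescenceTrace(
        name=name or Path(path).stem,
        times=df["time_s"].to_numpy(),
        emission=df["emission_au"].to_numpy(),
        meta={},
    )


def write_manifest(manifest: Mapping[str, Mapping], path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
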