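"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA for 3'UTR sequences (one record per gene id), BED6 for cross-link
tracks in transcript space (chrom = gene id, score = cDNA count), TSV for
annotation / expression / DE / truth tables and YAML for configuration.
Tabular writers prepend a ``# seed=<n>`` comment when a seed is given.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import CrosslinkTrack, UtrRecord


# ---------------------------------------------------------------- FASTA

def write_fasta(records: list[UtrRecord], path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" seed={seed}" if seed is not None else ""
            fh.write(f">{rec.gene_id}{desc}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ BED

def write_crosslink_bed(track: CrosslinkTrack, path: str | Path, seed: int | None = None) -> None:
    """BED6: gene_id, start, start+1, sample_id, cDNA count, '+'."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for gene in track.genes():
            vec = track.counts[gene]
            for pos in np.flatnonzero(vec):
                fh.write(f"{gene}\t{pos}\t{pos + 1}\t{track.sample_id}\t{vec[pos]}\t+\n")


def read_crosslink_bed(path: str | Path, lengths: dict[str, int] | None = None,
                       sample_id: str | None = None) -> CrosslinkTrack:
    """Read a BED6 cross-link file back into a dense track.

    ``lengths`` fixes per-gene vector lengths; without it each gene vector
    extends to its last observed position. Minus-strand rows are accepted
    (positions are already in transcript space) but flagged.
    """
    rows: list[tuple[str, int, int]] = []
    name = sample_id
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            gene, start, end = f[0], int(f[1]), int(f[2])
            if end != start + 1:
                raise ValueError(f"cross-link interval must be 1 nt wide: {line!r}")
            if name is None and len(f) > 3:
                name = f[3]
            rows.append((gene, start, int(f[4]) if len(f) > 4 else 1))
    track = CrosslinkTrack(name or "sample")
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for gene, pos, cnt in rows:
        by_gene.setdefault(gene, []).append((pos, cnt))
    for gene, hits in by_gene.items():
        n = (lengths.get(gene, max(p for p, _ in hits) + 1) if lengths
             else max(p for p, _ in hits) + 1)
        vec = np.zeros(n, dtype=np.int64)
        for pos, cnt in hits:
            if pos < n:
                vec[pos] += cnt
        track.set_gene(gene, vec)
    if lengths:
        for gene, n in lengths.items():
            if gene not in track.counts:
                track.set_gene(gene, np.zeros(n, dtype=np.int64))
    return track


# ------------------------------------------------------------------ TSV

def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ----------------------------------------------------------------- YAML

def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def records_to_annotation(records: list[UtrRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "utr_length": r.width,
            "regulation_class": r.regulation_class,
            "biotype": r.biotype,
            "pas_position": -1 if r.pas_position is None else r.pas_position,
        }
        for cond, v in sorted(r.tpm.items()):
            row[f"tpm_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
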