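"""Core in-memory containers shared across the analysis stages.

Coordinates are 0-based half-open throughout, in "transcript space": each
3'UTR is its own chromosome named by gene id, so position 0 is the first
nucleotide of the UTR and ``len(seq)`` is one past the 3' terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")


def rna_to_dna(kmer: str) -> str:
    """Motif groups are written in RNA (U); sequences are stored as DNA (T)."""
    return kmer.upper().replace("U", "T")


def dna_to_rna(kmer: str) -> str:
    return kmer.upper().replace("T", "U")


@dataclass
class UtrRecord:
    """One 3'UTR: sequence, regulation class and expression context.

    ``pas_position`` is the 0-based start of the terminal canonical
    poly(A) signal (AATAAA) within ``sequence``, or ``None`` when the UTR
    has no valid terminal PAS.
    """

    gene_id: str
    sequence: str
    regulation_class: str = "control"  # down | up | control
    tpm: dict[str, float] = field(default_factory=dict)
    pas_position: int | None = None
    biotype: str = "protein_coding"

    @property
    def width(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValueError(f"{self.gene_id}: invalid bases {sorted(bad)}")


class CrosslinkTrack:
    """Per-sample map (gene id, position) -> cDNA count.

    Internally one dense integer vector per gene; genes absent from the
    mapping have an implicit all-zero profile.
    """

    def __init__(self, sample_id: str, counts: dict[str, np.ndarray] | None = None):
        self.sample_id = sample_id
        self.counts: dict[str, np.ndarray] = {}
        if counts:
            for gene, vec in counts.items():
                self.set_gene(gene, vec)

    def set_gene(self, gene_id: str, vec: np.ndarray) -> None:
        arr = np.asarray(vec)
        if arr.ndim != 1:
            raise ValueError("per-gene count vector must be 1-D")
        if np.any(arr < 0):
            raise ValueError("cDNA counts must be non-negative")
        self.counts[gene_id] = arr.astype(np.int64)

    def get(self, gene_id: str, length: int | None = None) -> np.ndarray:
        if gene_id in self.counts:
            vec = self.counts[gene_id]
            if length is not None and len(vec) != length:
                out = np.zeros(length, dtype=np.int64)
                out[: min(length, len(vec))] = vec[: min(length, len(vec))]
                return out
            return vec
        if length is None:
            raise KeyError(gene_id)
        return np.zeros(length, dtype=np.int64)

    @property
    def library_size(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def genes(self) -> list[str]:
        return sorted(self.counts)

    def crosslink_positions(self, gene_id: str) -> np.ndarray:
        """Positions with at least one cDNA, ascending."""
        vec = self.counts.get(gene_id)
        if vec is None:
            return np.array([], dtype=np.int64)
        return np.flatnonzero(vec)

    @classmethod
    def merge(cls, tracks: list["CrosslinkTrack"], sample_id: str = "merged") -> "CrosslinkTrack":
        """Sum cDNA counts at overlapping positions across samples."""
        out = cls(sample_id)
        for t in tracks:
            for gene, vec in t.counts.items():
                if gene in out.counts:
                    a, b = out.counts[gene], vec
                    n = max(len(a), len(b))
                    merged = np.zeros(n, dtype=np.int64)
                    merged[: len(a)] += a
                    merged[: len(b)] += b
                    out.counts[gene] = merged
                else:
                    out.counts[gene] = vec.copy()
        return out
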