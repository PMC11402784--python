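"""Ground-truthed synthetic data emulating the study conditions.

The generator produces a small transcriptome of single-isoform 3'UTRs in
three regulation classes (down / up / control). Down-class UTRs carry an
elevated density of AUU trimers in the terminal window upstream of a
canonical poly(A) signal (PAS, AATAAA). Cross-link tracks are drawn from a
background + hotspot mixture; in the "primed" (MEK/FGF-stimulated-like)
condition the regulator's hotspots sit on the planted terminal AUU
positions of down-class genes, so binding relocates toward 3'UTR termini.
Conversion time courses follow exponential decay with known half-lives,
with down-class transcripts destabilized in the primed condition.

Everything is deterministic under ``SimConfig.seed``; per-generator RNG
streams are derived from the seed so stages do not perturb one another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import UtrRecord, CrosslinkTrack
from . import io as udio

CONDITIONS = ("naive", "primed")
CLASSES = ("down", "up", "control")
PLANTED_TRIMER = "ATT"  # AUU in RNA
HOTSPOT_HALF_WIDTH = 5  # nt around a hotspot center receiving hotspot reads

# fixed offsets for deriving independent RNG streams from the global seed
_STREAMS = {"transcriptome": 1, "crosslinks_naive": 2, "crosslinks_primed": 3,
            "slamseq": 4, "expression": 5, "kmer_families": 6}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    ``planted_motif_rates`` are the expected (Poisson) AUU-trimer counts in
    the ``terminal_window`` nt upstream of the PAS per class; the default
    down-class rate of 8 mirrors the observed median AUU valency of
    destabilized 3'UTR termini, against a background rate of 3.
    ``crosslink_depth`` is the expected number of cDNAs per gene per sample.
    """

    n_genes: int = 300
    utr_length_range: tuple[int, int] = (300, 600)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"down": 1 / 3, "up": 1 / 3, "control": 1 / 3})
    pas_motif: str = "AATAAA"
    planted_motif_rates: dict[str, float] = field(
        default_factory=lambda: {"down": 8.0, "up": 3.0, "control": 3.0})
    terminal_window: int = 100
    crosslink_depth: float = 60.0
    background_weight: float = 0.3
    primed_binding_boost: float = 2.0  # extra regulator binding on down-class
    halflife_range: tuple[float, float] = (2.0, 10.0)
    destabilization_factor: float = 2.0
    noise_sd: float = 0.02
    gc_content: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.utr_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("utr_length_range must be a positive interval")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if lo < self.terminal_window + len(self.pas_motif) + 20:
            raise ValueError(
                "utr_length_range lower bound must be >= terminal_window + "
                f"{len(self.pas_motif) + 20} to place the PAS and window")
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must lie in [0, 1]")
        if not (0 <= self.background_weight <= 1):
            raise ValueError("background_weight must lie in [0, 1]")
        h_lo, h_hi = self.halflife_range
        if h_lo <= 0 or h_hi < h_lo:
            raise ValueError("halflife_range must be a positive interval")
        if self.noise_sd < 0 or self.crosslink_depth < 0:
            raise ValueError("noise_sd and crosslink_depth must be >= 0")
        if self.destabilization_factor <= 0:
            raise ValueError("destabilization_factor must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["utr_length_range"] = list(d["utr_length_range"])
        d["halflife_range"] = list(d["halflife_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("utr_length_range", "halflife_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-gene truth the recovery tests compare against."""

    classes: dict[str, str]
    halflife: dict[str, dict[str, float]]  # gene -> condition -> hours
    motif_positions: dict[str, list[int]]  # planted AUU trimer starts
    hotspots: dict[str, dict[str, list[int]]]  # gene -> condition -> centers

    def genes(self) -> list[str]:
        return sorted(self.classes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes():
            rows.append({
                "gene_id": gene,
                "regulation_class": self.classes[gene],
                "halflife_naive": repr(self.halflife[gene]["naive"]),
                "halflife_primed": repr(self.halflife[gene]["primed"]),
                "motif_positions": ",".join(map(str, self.motif_positions[gene])),
                "hotspots_naive": ",".join(map(str, self.hotspots[gene]["naive"])),
                "hotspots_primed": ",".join(map(str, self.hotspots[gene]["primed"])),
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        def ints(s) -> list[int]:
            s = "" if pd.isna(s) else str(s)
            return [int(x) for x in s.split(",") if x != ""]

        classes, halflife, motifs, hotspots = {}, {}, {}, {}
        for _, r in df.iterrows():
            g = r["gene_id"]
            classes[g] = r["regulation_class"]
            halflife[g] = {"naive": float(r["halflife_naive"]),
                           "primed": float(r["halflife_primed"])}
            motifs[g] = ints(r["motif_positions"])
            hotspots[g] = {"naive": ints(r["hotspots_naive"]),
                           "primed": ints(r["hotspots_primed"])}
        return cls(classes, halflife, motifs, hotspots)

    def write(self, path: str | Path, seed: int | None = None) -> None:
        udio.write_table(self.to_frame(), path, seed=seed)

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#",
                                          float_precision="round_trip",
                                          dtype={"motif_positions": str,
                                                 "hotspots_naive": str,
                                                 "hotspots_primed": str}))


# ------------------------------------------------------------ transcriptome

def _class_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment; exact on divisible n."""
    raw = {c: n * proportions.get(c, 0.0) for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    rest = n - sum(counts.values())
    order = sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:rest]:
        counts[c] += 1
    return counts


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _scrub_spurious_pas(seq: list[str], pas: str, protected: set[int],
                        rng: np.random.Generator) -> None:
    """Mutate non-planted PAS occurrences so exactly one terminal PAS remains."""
    s = "".join(seq)
    start = 0
    while True:
        idx = s.find(pas, start)
        if idx < 0:
            break
        span = range(idx, idx + len(pas))
        if all(p in protected for p in span):
            start = idx + 1
            continue
        editable = [p for p in span if p not in protected]
        pos = editable[len(editable) // 2]
        seq[pos] = "C"  # AATAAA contains no C, so this cannot create a new PAS
        s = "".join(seq)
        start = idx
    return None


def generate_transcriptome(cfg: SimConfig) -> tuple[list[UtrRecord], GroundTruth]:
    """Generate 3'UTR records plus the ground truth used by recovery tests.

    Each record carries exactly one canonical PAS whose 3' end lies >= 20 nt
    from the UTR terminus. Down-class records receive AUU trimers planted at
    a higher Poisson rate within ``terminal_window`` nt upstream of the PAS.
    """
    cfg.validate()
    rng = cfg.rng("transcriptome")
    counts = _class_counts(cfg.n_genes, cfg.class_proportions)
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)

    lo, hi = cfg.utr_length_range
    h_lo, h_hi = cfg.halflife_range
    pas = cfg.pas_motif.upper()
    records: list[UtrRecord] = []
    classes: dict[str, str] = {}
    halflife: dict[str, dict[str, float]] = {}
    motif_positions: dict[str, list[int]] = {}
    hotspots: dict[str, dict[str, list[int]]] = {}

    for i, cls_label in enumerate(labels):
        gene = f"g{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = [b.decode() for b in _random_seq(rng, length, cfg.gc_content)]

        # terminal PAS: 3' end of the hexamer 20-40 nt from the UTR terminus
        max_d = min(40, length - len(pas) - cfg.terminal_window)
        dist = int(rng.integers(20, max(21, max_d + 1)))
        pas_start = length - dist - len(pas)
        seq[pas_start : pas_start + len(pas)] = list(pas)
        protected = set(range(pas_start, pas_start + len(pas)))

        # plant AUU trimers in the terminal window upstream of the PAS
        rate = float(cfg.planted_motif_rates.get(cls_label, 0.0))
        n_mot = int(rng.poisson(rate))
        win_lo = pas_start - cfg.terminal_window
        planted: list[int] = []
        candidates = list(range(win_lo, pas_start - 2))
        rng.shuffle(candidates)
        for start in candidates:
            if len(planted) >= n_mot:
                break
            if any(abs(start - p) < 3 for p in planted):
                continue
            seq[start : start + 3] = list(PLANTED_TRIMER)
            planted.append(start)
        planted.sort()
        for p in planted:
            protected.update(range(p, p + 3))

        _scrub_spurious_pas(seq, pas, protected, rng)

        h_naive = float(rng.uniform(h_lo, h_hi))
        h_primed = h_naive / cfg.destabilization_factor if cls_label == "down" else h_naive
        interior_hi = max(HOTSPOT_HALF_WIDTH + 1, win_lo - HOTSPOT_HALF_WIDTH)
        interior = sorted(int(rng.integers(HOTSPOT_HALF_WIDTH, interior_hi + 1))
                          for _ in range(2))
        terminal = planted if (cls_label == "down" and planted) else interior

        records.append(UtrRecord(gene_id=gene, sequence="".join(seq),
                                 regulation_class=cls_label,
                                 pas_position=pas_start))
        classes[gene] = cls_label
        halflife[gene] = {"naive": h_naive, "primed": h_primed}
        motif_positions[gene] = planted
        hotspots[gene] = {"naive": interior, "primed": terminal}

    truth = GroundTruth(classes, halflife, motif_positions, hotspots)
    return records, truth


# -------------------------------------------------------------- cross-links

def simulate_crosslinks(records: list[UtrRecord], truth: GroundTruth,
                        condition: str, cfg: SimConfig,
                        sample_id: str | None = None) -> CrosslinkTrack:
    """Draw a per-nucleotide cDNA-count track for one condition.

    Counts come from a mixture of uniform background (weight
    ``cfg.background_weight``) and hotspot components centred on the truth
    hotspots for the requested condition (within ±5 nt). In the primed
    condition the down-class hotspots are the planted terminal AUU
    positions, relocating signal toward 3'UTR termini.
    """
    cfg.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = cfg.rng(f"crosslinks_{condition}")
    track = CrosslinkTrack(sample_id or f"regulator_{condition}")
    for rec in records:
        vec = np.zeros(rec.width, dtype=np.int64)
        depth = cfg.crosslink_depth
        if condition == "primed" and truth.classes[rec.gene_id] == "down":
            depth *= cfg.primed_binding_boost
        total = int(rng.poisson(depth))
        spots = truth.hotspots[rec.gene_id][condition]
        for _ in range(total):
            if not spots or rng.random() < cfg.background_weight:
                pos = int(rng.integers(0, rec.width))
            else:
                center = spots[int(rng.integers(0, len(spots)))]
                pos = center + int(rng.integers(-HOTSPOT_HALF_WIDTH,
                                                HOTSPOT_HALF_WIDTH + 1))
                pos = min(max(pos, 0), rec.width - 1)
            vec[pos] += 1
        track.set_gene(rec.gene_id, vec)
    return track


# ------------------------------------------------------------------ SLAMseq

def simulate_slamseq(truth: GroundTruth, timepoints: list[float],
                     cfg: SimConfig, conditions: tuple[str, ...] = CONDITIONS
                     ) -> pd.DataFrame:
    """Normalized T>C conversion time courses under exponential decay.

    value(t) = exp(-lambda * t) + Gaussian noise (sd = cfg.noise_sd),
    truncated at 0, with lambda = ln2 / true half-life per condition.
    Returns a long table: gene, condition, timepoint_h, value.
    """
    cfg.validate()
    tps = np.asarray(sorted(timepoints), dtype=float)
    if np.any(tps < 0):
        raise ValueError("timepoints must be non-negative")
    if 0.0 not in tps:
        raise ValueError("timepoints must include 0")
    rng = cfg.rng("slamseq")
    rows = []
    for gene in truth.genes():
        for cond in conditions:
            lam = np.log(2) / truth.halflife[gene][cond]
            clean = np.exp(-lam * tps)
            noisy = clean + rng.normal(0.0, cfg.noise_sd, size=len(tps)) \
                if cfg.noise_sd > 0 else clean
            noisy = np.maximum(noisy, 0.0)
            for t, v in zip(tps, noisy):
                rows.append({"gene": gene, "condition": cond,
                             "timepoint_h": t, "value": v})
    return pd.DataFrame(rows)


# ------------------------------------------------------- expression and DE

def simulate_expression_and_de(truth: GroundTruth, cfg: SimConfig,
                               n_replicates: int = 2
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition TPM (log-normal, floored at 5) and a DE table whose
    log2FC / adjusted p are consistent with the true class labels."""
    cfg.validate()
    rng = cfg.rng("expression")
    log2_15 = np.log2(1.5)
    tpm_rows, de_rows = [], []
    for gene in truth.genes():
        cls_label = truth.classes[gene]
        base = 5.0 + float(rng.lognormal(mean=2.5, sigma=1.0))
        row = {"gene_id": gene}
        for cond in CONDITIONS:
            for rep in range(1, n_replicates + 1):
                row[f"tpm_{cond}_rep{rep}"] = base * float(rng.lognormal(0.0, 0.1))
        tpm_rows.append(row)
        if cls_label == "down":
            lfc = -(log2_15 + float(rng.exponential(0.5)))
            padj = float(rng.uniform(1e-6, 0.049))
        elif cls_label == "up":
            lfc = log2_15 + float(rng.exponential(0.5))
            padj = float(rng.uniform(1e-6, 0.049))
        else:
            lfc = float(rng.uniform(-0.49, 0.49))
            padj = float(rng.uniform(0.05, 1.0))
        de_rows.append({"gene_id": gene, "log2FC": lfc, "padj": padj,
                        "biotype": "protein_coding"})
    return pd.DataFrame(tpm_rows), pd.DataFrame(de_rows)


def attach_expression(records: list[UtrRecord], tpm: pd.DataFrame) -> None:
    """Store per-condition replicate-mean TPM on each record."""
    tpm = tpm.set_index("gene_id")
    for rec in records:
        if rec.gene_id not in tpm.index:
            continue
        for cond in CONDITIONS:
            cols = [c for c in tpm.columns if c.startswith(f"tpm_{cond}_")]
            rec.tpm[cond] = float(tpm.loc[rec.gene_id, cols].mean())


# -------------------------------------------------- k-mer family fixtures

KMER_FAMILIES = {
    "AUU": ["AUUAU", "UUAUU", "UAUUA", "AUUUA", "UUUAU", "AAUUU"],
    "WGG": ["AGGGA", "UGGGU", "GGGAG", "AGGGG", "UGGGG", "GGGUG"],
    "GAU": ["GAUGA", "AUGAU", "UGAUG", "GAUGG", "GGAUG", "GAUGU"],
}


def make_kmer_family_ranks(seed: int, families: dict[str, list[str]] | None = None,
                           rank_jitter: float = 1.5) -> pd.DataFrame:
    """Synthetic enriched-k-mer table from planted families.

    Families occupy separated rank strata (family means 40 apart) with
    Gaussian jitter, emulating motif groups that share both sequence
    composition and enrichment rank. Columns: kmer, family, rank.
    """
    families = families or KMER_FAMILIES
    rng = np.random.default_rng([seed, _STREAMS["kmer_families"]])
    rows = []
    for fi, (fam, kmers) in enumerate(sorted(families.items())):
        center = 10 + 40 * fi
        for km in kmers:
            rows.append({"kmer": km, "family": fam,
                         "rank": center + float(rng.normal(0, rank_jitter))})
    return pd.DataFrame(rows)
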