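"""k-mer motif-group discovery and positional motif analyses.

Enriched k-mers are found by comparing k-mer occurrence near cross-link
sites against seeded uniform-background draws from the same 3'UTRs
(a permutation z-score surrogate for positional k-mer enrichment
analysis). Enriched k-mers are clustered into motif groups with a
combined distance: substring-set Jaccard distance between k-mer sequences
and Euclidean distance between enrichment ranks, each standard-scaled and
min-max-scaled, joined by Pythagorean addition, then re-compared by
correlation distance and linked with UPGMA.

Sequences are stored as DNA (T); motif groups are expressed in RNA (U).
Conversion happens at the interface of every public operation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist

from .core import CrosslinkTrack, dna_to_rna, rna_to_dna
from .clip import smooth_profile, moving_average

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# --------------------------------------------------------------- encoding

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(len(arr), -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Code of the k-mer starting at each position; -1 where ambiguous."""
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        out = out * 4 + np.where(c < 0, 0, c)
        bad |= c < 0
    out[bad] = -1
    return out


def _decode_kmer(code: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


# -------------------------------------------------------- k-mer enrichment

@dataclass
class KmerStats:
    """Per-sample enriched k-mers (RNA alphabet) with rank and the offsets
    relative to cross-link sites at which each k-mer is over-represented."""
    sample_id: str
    table: pd.DataFrame  # kmer, score, p, rank
    relevant_positions: dict[str, list[int]]  # RNA kmer -> offsets


def kmer_enrichment(track: CrosslinkTrack, sequences: dict[str, str],
                    k: int = 5, half_window: int = 20, n_shuffle: int = 100,
                    seed: int = 0) -> KmerStats:
    """Permutation z-score k-mer enrichment around cross-link sites.

    For every k-mer, compares its occurrence count within +-half_window nt
    of cross-link sites against ``n_shuffle`` seeded draws of equally many
    positions placed uniformly within the same 3'UTRs. Score is the
    z-score against the background distribution; p is the empirical
    permutation tail probability (with a +1 pseudocount), so its floor is
    1/(n_shuffle+1). Relevant positions are start offsets (relative to the
    cross-link) where the observed per-offset count exceeds background
    mean + 2 sd. With fewer than 50 cross-links the background draw per
    round is widened tenfold.
    """
    rng = np.random.default_rng(seed)
    offsets = np.arange(-half_window, half_window - k + 2)
    n_off = len(offsets)
    n_kmers = 4 ** k

    codes = {g: _kmer_codes(seq, k) for g, seq in sequences.items()}
    sites = [(g, int(p)) for g in sorted(track.counts)
             for p in track.crosslink_positions(g) if g in codes]
    if not sites:
        raise ValueError("track has no cross-links on the given sequences")
    widen = 10 if len(sites) < 50 else 1
    if widen > 1:
        warnings.warn(f"only {len(sites)} cross-links; widening background "
                      "draws tenfold", stacklevel=2)

    def offset_codes(positions: list[tuple[str, int]]) -> np.ndarray:
        """Flat (kmer_code * n_off + offset_idx) indices, invalid removed."""
        chunks = []
        for g, p in positions:
            cg = codes[g]
            starts = p + offsets
            valid = (starts >= 0) & (starts < len(cg))
            cc = cg[starts[valid]]
            oi = np.flatnonzero(valid)
            keep = cc >= 0
            chunks.append(cc[keep] * n_off + oi[keep])
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)

    obs_off = np.bincount(offset_codes(sites), minlength=n_kmers * n_off
                          ).reshape(n_kmers, n_off)
    obs_tot = obs_off.sum(axis=1)

    per_gene = {}
    for g, _ in sites:
        per_gene[g] = per_gene.get(g, 0) + 1
    bg_off = np.zeros((n_shuffle, n_kmers, n_off))
    for r in range(n_shuffle):
        draw = [(g, int(pos)) for g, m in per_gene.items()
                for pos in rng.integers(0, len(sequences[g]), size=m * widen)]
        bg = np.bincount(offset_codes(draw), minlength=n_kmers * n_off
                         ).reshape(n_kmers, n_off) / widen
        bg_off[r] = bg
    bg_tot = bg_off.sum(axis=2)  # n_shuffle x n_kmers
    mu, sd = bg_tot.mean(axis=0), bg_tot.std(axis=0)
    z = np.where(obs_tot + mu > 0, (obs_tot - mu) / np.maximum(sd, 1e-9), 0.0)
    # empirical permutation p with a pseudocount; keeps the family-wise
    # minimum p calibrated at its 1/(n_shuffle+1) floor under the null
    exceed = (bg_tot >= obs_tot[None, :]).sum(axis=0)
    p = np.where(obs_tot + mu > 0, (1 + exceed) / (n_shuffle + 1), 1.0)

    mu_off, sd_off = bg_off.mean(axis=0), bg_off.std(axis=0)
    relevant = {}
    order = np.argsort(-z, kind="stable")
    rank = np.empty(n_kmers, dtype=int)
    rank[order] = np.arange(1, n_kmers + 1)
    rows = []
    for code in range(n_kmers):
        kmer = dna_to_rna(_decode_kmer(code, k))
        rows.append({"kmer": kmer, "score": z[code], "p": p[code],
                     "rank": rank[code]})
        hot = offsets[obs_off[code] > mu_off[code] + 2 * sd_off[code]]
        if len(hot):
            relevant[kmer] = [int(o) for o in hot]
    table = (pd.DataFrame(rows).sort_values("rank").reset_index(drop=True))
    return KmerStats(track.sample_id, table, relevant)


# ------------------------------------------------------ clustering distance

def substring_set(kmer: str) -> frozenset[str]:
    """All substrings with length strictly less than len(kmer), as a set."""
    kmer = kmer.upper()
    if not kmer:
        raise ValueError("empty k-mer")
    k = len(kmer)
    return frozenset(kmer[i:j] for i in range(k) for j in range(i + 1, min(i + k, k + 1))
                     if j - i < k)


def substring_jaccard_distance(kmer_a: str, kmer_b: str) -> float:
    """1 - Jaccard similarity of the proper-substring sets of two k-mers."""
    if len(kmer_a) != len(kmer_b):
        raise ValueError("k-mers must have equal length")
    sa, sb = substring_set(kmer_a), substring_set(kmer_b)
    return 1.0 - len(sa & sb) / len(sa | sb)


def jaccard_matrix(kmers: list[str]) -> np.ndarray:
    sets = [substring_set(k) for k in kmers]
    n = len(kmers)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / len(sets[i] | sets[j])
    return d


def rank_distance_matrix(ranks: np.ndarray) -> np.ndarray:
    r = np.asarray(ranks, dtype=float)
    return np.abs(r[:, None] - r[None, :])


def _scale(mat: np.ndarray) -> np.ndarray:
    """Standard scaling then min-max scaling, over all entries; preserves
    symmetry and keeps the (minimal) zero diagonal at 0."""
    sd = mat.std()
    z = (mat - mat.mean()) / sd if sd > 0 else np.zeros_like(mat)
    lo, hi = z.min(), z.max()
    return (z - lo) / (hi - lo) if hi > lo else np.zeros_like(mat)


def combine_distances(rank_matrix: np.ndarray, jaccard_matrix: np.ndarray
                      ) -> np.ndarray:
    """Pythagorean combination of the two scaled distance matrices."""
    for m in (rank_matrix, jaccard_matrix):
        m = np.asarray(m, dtype=float)
        if m.shape != rank_matrix.shape or m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrices must be square and same shape")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrices must have zero diagonal")
    a, b = _scale(np.asarray(rank_matrix, float)), _scale(np.asarray(jaccard_matrix, float))
    return np.sqrt(a ** 2 + b ** 2)


# -------------------------------------------------------------- clustering

@dataclass
class MotifGroup:
    name: str  # WGG | GAU | AUU | other
    kmers: list[str] = field(default_factory=list)  # RNA alphabet
    provenance: str = ""

    def dna_kmers(self) -> list[str]:
        return [rna_to_dna(k) for k in self.kmers]


_NAME_TRIMERS = {"AUU": ("AUU", "UUA", "UAU", "UUU"),
                 "WGG": ("GGG", "AGG", "UGG", "GGA", "GGU"),
                 "GAU": ("GAU", "AUG", "UGA")}


def name_motif_group(kmers: list[str]) -> str:
    """Name a k-mer cluster by the dominant diagnostic trimer family."""
    votes = {name: 0 for name in _NAME_TRIMERS}
    for km in kmers:
        km = dna_to_rna(km)
        for name, trimers in _NAME_TRIMERS.items():
            votes[name] += sum(km[i : i + 3] in trimers for i in range(len(km) - 2))
    best = max(sorted(votes), key=lambda n: votes[n])
    return best if votes[best] > 0 else "other"


def cluster_kmers(combined: np.ndarray, kmers: list[str], n_clusters: int = 4,
                  merge_g_rich: bool = False, provenance: str = ""
                  ) -> list[MotifGroup]:
    """UPGMA clustering of k-mers on the combined distance matrix.

    Rows of the combined matrix are re-compared by correlation distance
    (the matrix is treated as a feature embedding), linked with UPGMA
    (average linkage) and the tree is cut into ``n_clusters`` flat
    clusters. Constant rows, whose correlation distance is undefined,
    become singleton groups with a warning. With ``merge_g_rich`` the
    G-rich clusters (AGGG-like and UGGG-like) are merged into one WGG
    group, mirroring the post-hoc merge of similar G-rich motif groups.
    """
    combined = np.asarray(combined, dtype=float)
    if len(kmers) < n_clusters:
        raise ValueError("need at least n_clusters k-mers")
    kmers = [dna_to_rna(k) for k in kmers]
    var = combined.var(axis=1)
    const = np.flatnonzero(var == 0)
    active = np.flatnonzero(var > 0)
    if len(const):
        warnings.warn(f"{len(const)} k-mers have constant distance rows; "
                      "assigned singleton clusters", stacklevel=2)
    labels = np.zeros(len(kmers), dtype=int)
    n_main = min(n_clusters, len(active))
    if len(active) >= 2 and n_main >= 1:
        sub = combined[np.ix_(active, active)]
        z = linkage(pdist(sub, metric="correlation"), method="average")
        labels[active] = fcluster(z, t=n_main, criterion="maxclust")
    elif len(active) == 1:
        labels[active] = 1
    next_label = labels.max() + 1
    for i in const:
        labels[i] = next_label
        next_label += 1

    groups = []
    for lab in sorted(set(labels[labels > 0])):
        members = [kmers[i] for i in np.flatnonzero(labels == lab)]
        groups.append(MotifGroup(name_motif_group(members), sorted(members),
                                 provenance))
    if merge_g_rich:
        g_rich = [g for g in groups if g.name == "WGG"]
        if len(g_rich) > 1:
            merged = MotifGroup("WGG", sorted(set(itertools.chain(
                *[g.kmers for g in g_rich]))), provenance)
            groups = [g for g in groups if g.name != "WGG"] + [merged]
    return groups


# ----------------------------------------------------- coverage summaries

def _group_coverage_mask(seq: str, group: MotifGroup) -> np.ndarray:
    """Boolean per-nucleotide mask: covered by any group k-mer window."""
    mask = np.zeros(len(seq), dtype=bool)
    for km in group.dna_kmers():
        k = len(km)
        start = seq.find(km)
        while start >= 0:
            mask[start : start + k] = True
            start = seq.find(km, start + 1)
    return mask


def motif_coverage_around_crosslinks(track: CrosslinkTrack,
                                     sequences: dict[str, str],
                                     group: MotifGroup, half_window: int = 300,
                                     cap: int = 20, smooth_window: int = 20
                                     ) -> pd.DataFrame:
    """Percentage of (capped) cDNA-weighted cross-links whose sequence has
    a group k-mer covering each offset in [-half_window, +half_window].

    cDNA weights are capped at ``cap`` so a handful of very deep
    cross-link sites cannot dominate; the profile is smoothed with a
    triangular rolling mean (``smooth_window`` nt).
    """
    if not group.kmers:
        raise ValueError("motif group is empty")
    masks = {g: _group_coverage_mask(seq, group) for g, seq in sequences.items()}
    n_off = 2 * half_window + 1
    covered = np.zeros(n_off)
    total = 0.0
    for g in sorted(track.counts):
        if g not in masks:
            continue
        vec = track.counts[g]
        mask = masks[g]
        for pos in np.flatnonzero(vec):
            w = min(int(vec[pos]), cap)
            total += w
            lo = pos - half_window
            src_lo, src_hi = max(lo, 0), min(pos + half_window + 1, len(mask))
            covered[src_lo - lo : src_hi - lo] += w * mask[src_lo:src_hi]
    if total == 0:
        raise ValueError("no cross-links fall on the given sequences")
    pct = 100.0 * covered / total
    return pd.DataFrame({"offset": np.arange(-half_window, half_window + 1),
                         "pct": pct,
                         "pct_smoothed": smooth_profile(pct, smooth_window)})


def motif_region_coverage(sequences: dict[str, str], group: MotifGroup,
                          regions: list[tuple[str, int, int]], bin_nt: int = 10
                          ) -> np.ndarray:
    """Mean per-bin percentage of nucleotides covered by group k-mers.

    Regions are (gene, start, end) within the sequences; the last partial
    bin is normalized by its true length. Bins are aligned from the region
    start and averaged across regions that reach each bin.
    """
    if not group.kmers:
        raise ValueError("motif group is empty")
    masks = {g: _group_coverage_mask(seq, group) for g, seq in sequences.items()}
    per_region = []
    for gene, start, end in regions:
        if gene not in masks:
            raise KeyError(gene)
        if not (0 <= start < end <= len(masks[gene])):
            raise ValueError(f"region out of bounds for {gene}")
        seg = masks[gene][start:end]
        n_bins = int(np.ceil(len(seg) / bin_nt))
        vals = np.empty(n_bins)
        for b in range(n_bins):
            chunk = seg[b * bin_nt : (b + 1) * bin_nt]
            vals[b] = 100.0 * chunk.mean()
        per_region.append(vals)
    width = max(len(v) for v in per_region)
    acc = np.zeros(width)
    n = np.zeros(width)
    for vals in per_region:
        acc[: len(vals)] += vals
        n[: len(vals)] += 1
    return acc / np.maximum(n, 1)


# ---------------------------------------------------------- PAS anchoring

def locate_terminal_pas(sequence: str, pas: str = "AATAAA",
                        min_distance_from_end: int = 20) -> int | None:
    """Rightmost exact PAS whose 3' end lies >= 20 nt from the terminus."""
    seq = rna_to_dna(sequence)
    pas = rna_to_dna(pas)
    idx = seq.rfind(pas)
    while idx >= 0:
        if len(seq) - (idx + len(pas)) >= min_distance_from_end:
            return idx
        idx = seq.rfind(pas, 0, idx)
    return None


def trimer_valency(sequences: dict[str, str], trimer: str = "AUU",
                   window: int = 100, pas: str = "AATAAA"
                   ) -> tuple[dict[str, int], list[str]]:
    """Overlapping trimer count in the ``window`` nt upstream of the
    terminal PAS of each sequence; sequences without a valid PAS are
    excluded and reported."""
    tri = rna_to_dna(trimer)
    counts, excluded = {}, []
    for gene, seq in sequences.items():
        pos = locate_terminal_pas(seq, pas)
        if pos is None:
            excluded.append(gene)
            continue
        region = rna_to_dna(seq)[max(0, pos - window) : pos]
        counts[gene] = sum(region[i : i + 3] == tri for i in range(len(region) - 2))
    return counts, excluded


# ------------------------------------------------------------ binding sites

@dataclass
class BindingSite:
    gene_id: str
    start: int
    end: int  # half-open
    group: str
    support: int  # summed cDNA of contributing cross-links


def assign_binding_sites(merged_track: CrosslinkTrack,
                         sequences: dict[str, str], group: MotifGroup,
                         relevant_positions: dict[str, list[int]],
                         flank: int = 20) -> list[BindingSite]:
    """Motif-based binding sites: a site is emitted where a group k-mer
    starts at one of its relevant offsets within +-flank nt of a
    cross-link. Overlapping same-group sites are merged; support sums the
    cDNA counts of the distinct contributing cross-links."""
    sites: list[BindingSite] = []
    for gene in sorted(merged_track.counts):
        seq = sequences.get(gene)
        if seq is None:
            continue
        vec = merged_track.counts[gene]
        candidates: list[tuple[int, int, int]] = []  # start, end, xlink pos
        xlinks = np.flatnonzero(vec)
        for km in group.dna_kmers():
            rel = set(relevant_positions.get(dna_to_rna(km), []))
            if not rel:
                continue
            k = len(km)
            start = seq.find(km)
            while start >= 0:
                for p in xlinks:
                    off = start - int(p)
                    if abs(off) <= flank and off in rel:
                        candidates.append((start, start + k, int(p)))
                start = seq.find(km, start + 1)
        candidates.sort()
        cur = None
        contributing: set[int] = set()
        for start, end, p in candidates:
            if cur is None:
                cur = [start, end]
                contributing = {p}
            elif start < cur[1]:  # overlap
                cur[1] = max(cur[1], end)
                contributing.add(p)
            else:
                sites.append(BindingSite(gene, cur[0], cur[1], group.name,
                                         int(sum(vec[q] for q in contributing))))
                cur = [start, end]
                contributing = {p}
        if cur is not None:
            sites.append(BindingSite(gene, cur[0], cur[1], group.name,
                                     int(sum(vec[q] for q in contributing))))
    return sites


# ------------------------------------------------------------------ peaks

def merge_peaks(peaks: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge book-ended or overlapping intervals within one peak set."""
    for _, s, e in peaks:
        if s > e:
            raise ValueError("peak start > end")
    merged: list[tuple[str, int, int]] = []
    for gene, s, e in sorted(peaks):
        if merged and merged[-1][0] == gene and s <= merged[-1][2]:
            g, ms, me = merged[-1]
            merged[-1] = (g, ms, max(me, e))
        else:
            merged.append((gene, s, e))
    return merged


def merge_and_overlap_peaks(peaks_a: list[tuple[str, int, int]],
                            peaks_b: list[tuple[str, int, int]]
                            ) -> tuple[list, list, list[bool]]:
    """Merge each set, then classify each merged a-peak as overlapping b
    by at least 1 nt of intersection (book-ended pairs do not count)."""
    ma, mb = merge_peaks(peaks_a), merge_peaks(peaks_b)
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for gene, s, e in mb:
        by_gene.setdefault(gene, []).append((s, e))
    flags = [any(s < be and bs < e for bs, be in by_gene.get(gene, []))
             for gene, s, e in ma]
    return ma, mb, flags


# ---------------------------------------------- nucleotide composition

def nucleotide_composition_around_pas(sequences: dict[str, str],
                                      upstream: int = 100, downstream: int = 20,
                                      pas: str = "AATAAA", smooth_window: int = 5
                                      ) -> pd.DataFrame:
    """Per-offset percentage of sequences carrying each base around the
    terminal PAS (offset 0 = PAS start; the window runs ``upstream`` nt
    before the PAS to ``downstream`` nt past its 3' end). Percentages sum
    to 100 per offset before the 5-nt rolling-mean smoothing."""
    valid = {g: (s, locate_terminal_pas(s, pas)) for g, s in sequences.items()}
    valid = {g: (s, p) for g, (s, p) in valid.items() if p is not None}
    if not valid:
        raise ValueError("no sequences with a valid terminal PAS")
    offsets = np.arange(-upstream, len(pas) + downstream)
    counts = {b: np.zeros(len(offsets)) for b in "ACGT"}
    denom = np.zeros(len(offsets))
    for g, (seq, p) in valid.items():
        seq = rna_to_dna(seq)
        for i, off in enumerate(offsets):
            pos = p + off
            if 0 <= pos < len(seq) and seq[pos] in counts:
                counts[seq[pos]][i] += 1
                denom[i] += 1
    data = {"offset": offsets}
    for b in "ACGT":
        pct = 100.0 * counts[b] / np.maximum(denom, 1)
        data[b] = pct
        data[f"{b}_smoothed"] = moving_average(pct, smooth_window)
    return pd.DataFrame(data)
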