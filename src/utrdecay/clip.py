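"""Normalization and positional summaries of cross-link tracks.

Cross-link counts are normalized to CPM (cross-links per million, library
depth) and then within each gene to its expression (gene-level TPM),
giving CPM-per-TPM coverage. Positional summaries anchor regions on the
terminal PAS, the 3'UTR terminus or arbitrary per-gene anchor points and
average smoothed per-region profiles with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import triang

from .core import CrosslinkTrack, UtrRecord


# ------------------------------------------------------------- expression

def gene_level_tpm(replicates: list[pd.DataFrame]) -> pd.Series:
    """Gene-level TPM: per replicate, sum transcript TPM within each gene;
    then average the per-gene sums across replicates.

    Each replicate table needs columns transcript_id, gene_id, tpm.
    Transcripts without a gene id are excluded with a warning.
    """
    sums = []
    for rep in replicates:
        rep = rep.copy()
        missing = rep["gene_id"].isna() | (rep["gene_id"].astype(str) == "")
        if missing.any():
            warnings.warn(f"excluding {int(missing.sum())} transcripts without "
                          "a gene id", stacklevel=2)
            rep = rep[~missing]
        sums.append(rep.groupby("gene_id")["tpm"].sum())
    return pd.concat(sums, axis=1).mean(axis=1).rename("tpm")


def normalize_coverage(track: CrosslinkTrack, records: list[UtrRecord],
                       expr: dict[str, float] | pd.Series
                       ) -> dict[str, np.ndarray]:
    """Per-gene positional coverage in CPM per TPM.

    value(pos) = count(pos) * 1e6 / library_size / TPM(gene). Genes with
    zero or missing TPM are dropped with a warning.
    """
    lib = track.library_size
    if lib <= 0:
        raise ValueError("track has zero library size")
    expr = dict(expr)
    out: dict[str, np.ndarray] = {}
    dropped = []
    for rec in records:
        tpm = expr.get(rec.gene_id, 0.0)
        if tpm is None or tpm <= 0 or not np.isfinite(tpm):
            dropped.append(rec.gene_id)
            continue
        counts = track.get(rec.gene_id, rec.width).astype(float)
        out[rec.gene_id] = counts * 1e6 / lib / tpm
    if dropped:
        warnings.warn(f"dropped {len(dropped)} regions with TPM <= 0",
                      stacklevel=2)
    return out


# -------------------------------------------------------------- smoothing

def smooth_profile(values: np.ndarray, window: int = 20,
                   shape: str = "triangular") -> np.ndarray:
    """Centered weighted rolling mean with edge fill.

    The kernel (triangular by default, boxcar for shape='flat') is
    normalized to unit weight, so a constant input returns the identical
    constant. Edge positions where the full window does not fit take the
    nearest valid smoothed value. A window longer than the series returns
    the input unsmoothed with a warning.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return v.copy()
    if window > len(v):
        warnings.warn("smoothing window exceeds series length; returning "
                      "unsmoothed values", stacklevel=2)
        return v.copy()
    if shape == "triangular":
        kernel = triang(window)
    elif shape == "flat":
        kernel = np.ones(window)
    else:
        raise ValueError(f"unknown window shape {shape!r}")
    kernel = kernel / kernel.sum()
    core = np.convolve(v, kernel, mode="valid")  # length n - window + 1
    out = np.empty_like(v)
    start = (window - 1) // 2
    out[start : start + len(core)] = core
    out[:start] = core[0]
    out[start + len(core):] = core[-1]
    return out


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Plain centered moving average with shrinking edges (min_periods=1)."""
    return (pd.Series(np.asarray(values, dtype=float))
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


# ------------------------------------------------------------ metaprofile

@dataclass
class Metaprofile:
    anchor: str
    offsets: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_regions: int
    region_matrix: np.ndarray  # regions x offsets, NaN outside bounds
    gene_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
                             "n": self.n_regions})


def pas_anchors(records: list[UtrRecord]) -> dict[str, int]:
    return {r.gene_id: r.pas_position for r in records if r.pas_position is not None}


def terminus_anchors(records: list[UtrRecord]) -> dict[str, int]:
    return {r.gene_id: r.width for r in records}


def _anchored_window(profile: np.ndarray, anchor: int,
                     span: tuple[int, int]) -> np.ndarray:
    """Slice profile[anchor+span[0] : anchor+span[1]], NaN out of bounds."""
    lo, hi = span
    out = np.full(hi - lo, np.nan)
    a, b = anchor + lo, anchor + hi
    src_lo, src_hi = max(a, 0), min(b, len(profile))
    if src_hi > src_lo:
        out[src_lo - a : src_hi - a] = profile[src_lo:src_hi]
    return out


def _smooth_with_nans(row: np.ndarray, window: int) -> np.ndarray:
    out = row.copy()
    valid = np.flatnonzero(~np.isnan(row))
    if len(valid) == 0:
        return out
    lo, hi = valid[0], valid[-1] + 1
    seg = row[lo:hi]
    if window <= len(seg):
        out[lo:hi] = smooth_profile(seg, window)
    return out


def metaprofile(track: CrosslinkTrack, records: list[UtrRecord],
                anchors: dict[str, int], span: tuple[int, int],
                expr: dict[str, float] | pd.Series, anchor_name: str = "custom",
                min_length: int = 0, smooth_window: int = 20,
                n_boot: int = 1000, seed: int = 0) -> Metaprofile:
    """Mean CPM-per-TPM coverage around per-gene anchor points.

    Per region: normalize, take the anchored window, smooth (triangular,
    ``smooth_window`` nt), then average across regions per offset with a
    bootstrap 95% CI (regions resampled, percentile method, seeded).
    """
    norm = normalize_coverage(track, records, expr)
    rows, genes = [], []
    for rec in records:
        if rec.width < min_length or rec.gene_id not in anchors:
            continue
        if rec.gene_id not in norm:
            continue
        win = _anchored_window(norm[rec.gene_id], anchors[rec.gene_id], span)
        rows.append(_smooth_with_nans(win, smooth_window))
        genes.append(rec.gene_id)
    if not rows:
        raise ValueError("no regions survive the metaprofile filters")
    mat = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(rows), size=(n_boot, len(rows)))
        boots = np.nanmean(mat[idx], axis=1)  # n_boot x offsets
        ci_lo = np.nanpercentile(boots, 2.5, axis=0)
        ci_hi = np.nanpercentile(boots, 97.5, axis=0)
    offsets = np.arange(span[0], span[1])
    return Metaprofile(anchor_name, offsets, mean, ci_lo, ci_hi, len(rows),
                       mat, genes)


# ------------------------------------------------- transcript-region bins

def bin_boundaries(length: int, n_bins: int) -> np.ndarray:
    """Equal-width bins; the first (length mod n_bins) bins get one extra
    nucleotide. For length < n_bins, repeated boundaries yield zero-width
    bins (flagged by the caller)."""
    if length >= n_bins:
        base, rem = divmod(length, n_bins)
        widths = np.full(n_bins, base, dtype=int)
        widths[:rem] += 1
        return np.concatenate([[0], np.cumsum(widths)])
    return np.floor(np.linspace(0, length, n_bins + 1)).astype(int)


def transcript_binned_metaprofile(track: CrosslinkTrack,
                                  regions: dict[str, dict[str, tuple[int, int]]],
                                  records: list[UtrRecord],
                                  expr: dict[str, float] | pd.Series,
                                  n_bins: int = 100, smooth_bins: int = 10
                                  ) -> dict[str, pd.DataFrame]:
    """Per-region-type 100-bin profile of normalized cross-link coverage.

    ``regions`` maps gene id -> region name (e.g. 5'UTR/CDS/3'UTR) ->
    (start, end) in that gene's coordinate space. Bin value = normalized
    count sum / bin width, averaged over genes; a rolling mean over
    ``smooth_bins`` bins gives the plotted line.
    """
    norm = normalize_coverage(track, records, expr)
    by_region: dict[str, list[np.ndarray]] = {}
    flagged: list[str] = []
    for gene, parts in regions.items():
        if gene not in norm:
            continue
        prof = norm[gene]
        for name, (start, end) in parts.items():
            if end <= start:
                raise ValueError(f"empty region {name} for {gene}")
            seg = prof[start:end]
            edges = bin_boundaries(len(seg), n_bins)
            widths = np.diff(edges)
            if np.any(widths == 0):
                flagged.append(f"{gene}:{name}")
            vals = np.add.reduceat(seg, edges[:-1]) if len(seg) else np.zeros(n_bins)
            # reduceat on a repeated boundary returns the element at it; zero out
            vals = np.where(widths > 0, vals / np.maximum(widths, 1), 0.0)
            by_region.setdefault(name, []).append(vals)
    if flagged:
        warnings.warn(f"{len(flagged)} regions shorter than {n_bins} nt binned "
                      "with repeated boundaries", stacklevel=2)
    out = {}
    for name, rows in by_region.items():
        mean = np.vstack(rows).mean(axis=0)
        out[name] = pd.DataFrame({"bin": np.arange(1, n_bins + 1), "mean": mean,
                                  "smoothed": moving_average(mean, smooth_bins)})
    return out


# ----------------------------------------------------------- UTR heat map

def per_utr_heatmap(track: CrosslinkTrack, records: list[UtrRecord],
                    expr: dict[str, float] | pd.Series, window: int = 10
                    ) -> dict[str, object]:
    """Per-UTR smoothed min-max-normalized signal rows plus abundance.

    Rows are moving-average smoothed (window nt) raw counts, min-max
    scaled to [0, 1]; constant rows (including all-zero) map to all-zero.
    The abundance column is total CPM / (length x TPM).
    """
    lib = track.library_size
    expr = dict(expr)
    max_len = max((r.width for r in records), default=0)
    mat = np.full((len(records), max_len), np.nan)
    pas_marks, abundance, genes = [], [], []
    for i, rec in enumerate(records):
        counts = track.get(rec.gene_id, rec.width).astype(float)
        sm = moving_average(counts, window) if window > 1 else counts
        lo, hi = sm.min(), sm.max()
        row = (sm - lo) / (hi - lo) if hi > lo else np.zeros_like(sm)
        mat[i, : rec.width] = row
        pas_marks.append(rec.pas_position)
        tpm = expr.get(rec.gene_id, np.nan)
        cpm = counts.sum() * 1e6 / lib if lib > 0 else 0.0
        abundance.append(cpm / (rec.width * tpm) if tpm and np.isfinite(tpm)
                         and tpm > 0 else np.nan)
        genes.append(rec.gene_id)
    return {"matrix": mat, "pas_positions": pas_marks,
            "abundance": np.array(abundance), "gene_ids": genes}


# --------------------------------------------------------- binned log2 FC

def binned_log2fc(track_a: CrosslinkTrack, track_b: CrosslinkTrack,
                  records: list[UtrRecord], bin_nt: int = 20,
                  span: int = 500) -> pd.DataFrame:
    """Per-bin log2 fold change of within-region cross-link percentages.

    For each gene's terminal ``span`` nt: raw counts per ``bin_nt`` bin are
    converted to the percentage of that region's counts per condition; a
    pseudocount of 1 is added to each percentage before the ratio
    log2((pct_b + 1) / (pct_a + 1)).
    """
    n_bins = span // bin_nt
    rows = []
    for rec in records:
        if rec.width < span:
            continue
        start = rec.width - span
        seg_a = track_a.get(rec.gene_id, rec.width)[start:].astype(float)
        seg_b = track_b.get(rec.gene_id, rec.width)[start:].astype(float)
        edges = np.arange(0, span + 1, bin_nt)
        ca = np.add.reduceat(seg_a, edges[:-1])
        cb = np.add.reduceat(seg_b, edges[:-1])
        pa = 100.0 * ca / ca.sum() if ca.sum() > 0 else np.zeros(n_bins)
        pb = 100.0 * cb / cb.sum() if cb.sum() > 0 else np.zeros(n_bins)
        lfc = np.log2((pb + 1.0) / (pa + 1.0))
        for b in range(n_bins):
            rows.append({"gene_id": rec.gene_id, "bin": b,
                         "offset_from_terminus": -span + b * bin_nt,
                         "pct_a": pa[b], "pct_b": pb[b], "log2fc": lfc[b]})
    return pd.DataFrame(rows)


# ------------------------------------------------------ terminal abundance

def terminal_abundance(tracks: list[CrosslinkTrack], records: list[UtrRecord],
                       expr: dict[str, float] | pd.Series, window: int = 300,
                       min_length: int = 800, min_tpm: float = 1.0,
                       min_cdnas: int = 5
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Normalized cross-link abundance at the 3'UTR start vs terminus.

    Windows: first ``window`` nt (downstream of the stop codon) and last
    ``window`` nt (upstream of the terminus). A UTR survives only if it is
    >= min_length nt, its gene's expression is >= min_tpm, and every track
    has >= min_cdnas cDNAs in BOTH windows. Quantification uses the merged
    track, CPM- and TPM-normalized. Returns (table, per-filter exclusions).
    """
    merged = CrosslinkTrack.merge(tracks)
    lib = merged.library_size
    expr = dict(expr)
    tally = {"length": 0, "expression": 0, "min_cdnas": 0, "kept": 0}
    rows = []
    for rec in records:
        if rec.width < min_length:
            tally["length"] += 1
            continue
        tpm = expr.get(rec.gene_id, 0.0)
        if not tpm or tpm < min_tpm:
            tally["expression"] += 1
            continue
        s0, s1 = 0, window
        t0, t1 = rec.width - window, rec.width
        ok = all(int(t.get(rec.gene_id, rec.width)[s0:s1].sum()) >= min_cdnas and
                 int(t.get(rec.gene_id, rec.width)[t0:t1].sum()) >= min_cdnas
                 for t in tracks)
        if not ok:
            tally["min_cdnas"] += 1
            continue
        counts = merged.get(rec.gene_id, rec.width).astype(float)
        norm = 1e6 / lib / tpm if lib > 0 else 0.0
        rows.append({"gene_id": rec.gene_id,
                     "regulation_class": rec.regulation_class,
                     "start_window": counts[s0:s1].sum() * norm,
                     "terminal_window": counts[t0:t1].sum() * norm})
        tally["kept"] += 1
    return pd.DataFrame(rows), tally
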