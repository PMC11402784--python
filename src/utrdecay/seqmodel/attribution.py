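"""Additive per-nucleotide attribution and its positional summaries.

Attribution uses integrated gradients against the all-N baseline (the
all-zero one-hot row): the input gradient of the chosen class logit is
averaged along the straight path from baseline to input and multiplied by
the input. Because the baseline is zero, attributions are additive and
their per-sequence sum approximates the logit difference from baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..clip import bin_boundaries
from .autodiff import Tensor
from .model import CLASS_ORDER, SequenceClassifier


def attribute(model: SequenceClassifier, X: np.ndarray, target_class: str = "down",
              n_steps: int = 16, batch: int = 64) -> np.ndarray:
    """Integrated-gradients attribution matrices, shape = X.shape.

    ``target_class`` selects the logit that is decomposed ('down' or
    'up'). Returns position x 4 scores per sequence; entries are nonzero
    only at observed (one-hot) positions since the baseline is all-zero.
    """
    cls = CLASS_ORDER.index(target_class)
    alphas = (np.arange(1, n_steps + 1) / n_steps)[:, None, None, None]
    out = np.zeros_like(X, dtype=float)
    for i in range(0, len(X), batch):
        xb = X[i : i + batch]
        grad_sum = np.zeros_like(xb, dtype=float)
        for alpha in alphas[:, 0, 0, 0]:
            xt = Tensor(alpha * xb, requires_grad=True)
            logits = model.logits(xt, training=False)
            sel = np.zeros_like(logits.data)
            sel[:, cls] = 1.0
            logits.backward(sel)
            grad_sum += xt.grad
        out[i : i + batch] = xb * grad_sum / n_steps
    return out


def completeness_correlation(model: SequenceClassifier, X: np.ndarray,
                             attr: np.ndarray, target_class: str = "down"
                             ) -> float:
    """Spearman correlation between per-sequence attribution sums and the
    logit difference from the all-N baseline (loose completeness check)."""
    from scipy.stats import spearmanr

    cls = CLASS_ORDER.index(target_class)
    logit_x = model.logits(Tensor(X)).data[:, cls]
    logit_0 = model.logits(Tensor(np.zeros_like(X))).data[:, cls]
    sums = attr.sum(axis=(1, 2))
    rho, _ = spearmanr(sums, logit_x - logit_0)
    return float(rho)


# ------------------------------------------------------------- summaries

def _bin_edges(n_positions: int, n_bins: int) -> np.ndarray:
    return bin_boundaries(n_positions, n_bins)


def position_scores(attr_row: np.ndarray) -> np.ndarray:
    """Per-position score: the attribution of the observed nucleotide."""
    return attr_row.sum(axis=1)


def summarize_trimer_importance(attrs: np.ndarray, sequences: list[str],
                                n_bins: int = 100) -> pd.DataFrame:
    """Per-trimer positional importance profile over 100 relative bins.

    Padding is removed per sequence; a sliding 3-nt window (step 1)
    assigns the window's mean score to the trimer present there; window
    start positions are grouped into 100 relative bins, scores within a
    bin are summed and normalized by bin width, and the profile is the
    mean over sequences. Trimers never observed are absent.
    """
    acc: dict[str, np.ndarray] = {}
    n_seq = 0
    for attr_row, seq in zip(attrs, sequences):
        L = len(seq)
        if L < 3:
            continue
        n_seq += 1
        scores = position_scores(attr_row[:L])
        win = np.array([scores[i : i + 3].mean() for i in range(L - 2)])
        edges = _bin_edges(L - 2, n_bins)
        widths = np.maximum(np.diff(edges), 1)
        starts = np.searchsorted(edges[1:], np.arange(L - 2), side="right")
        for i in range(L - 2):
            tri = seq[i : i + 3].upper()
            if any(b not in "ACGT" for b in tri):
                continue
            if tri not in acc:
                acc[tri] = np.zeros(n_bins)
            acc[tri][starts[i]] += win[i] / widths[starts[i]]
    if n_seq == 0:
        raise ValueError("no sequences of length >= 3")
    data = {tri: vals / n_seq for tri, vals in sorted(acc.items())}
    return pd.DataFrame(data, index=pd.RangeIndex(1, n_bins + 1, name="bin")).T


def trimer_occupancy(sequences: list[str], n_bins: int = 100) -> pd.DataFrame:
    """Occupancy counterpart of summarize_trimer_importance: the binned
    trimer count map, i.e. what the summary returns when every
    per-nucleotide attribution equals 1 (used as an independent oracle)."""
    acc: dict[str, np.ndarray] = {}
    n_seq = 0
    for seq in sequences:
        L = len(seq)
        if L < 3:
            continue
        n_seq += 1
        edges = _bin_edges(L - 2, n_bins)
        widths = np.maximum(np.diff(edges), 1)
        starts = np.searchsorted(edges[1:], np.arange(L - 2), side="right")
        for i in range(L - 2):
            tri = seq[i : i + 3].upper()
            if any(b not in "ACGT" for b in tri):
                continue
            if tri not in acc:
                acc[tri] = np.zeros(n_bins)
            acc[tri][starts[i]] += 1.0 / widths[starts[i]]
    data = {tri: vals / n_seq for tri, vals in sorted(acc.items())}
    return pd.DataFrame(data, index=pd.RangeIndex(1, n_bins + 1, name="bin")).T


def positional_importance(attrs: np.ndarray, lengths: np.ndarray,
                          n_bins: int = 100) -> pd.DataFrame:
    """Mean per-nucleotide importance across 100 length-relative bins.

    Per sequence, nucleotide-level scores (per observed base identity) are
    assigned to bins by relative position and summed within each bin; the
    heat-map rows are cross-sequence means per base.
    """
    bases = "ACGT"
    acc = np.zeros((4, n_bins))
    n_seq = 0
    for attr_row, L in zip(attrs, lengths):
        L = int(L)
        if L < 1:
            continue
        n_seq += 1
        edges = _bin_edges(L, n_bins)
        starts = np.searchsorted(edges[1:], np.arange(L), side="right")
        for b in range(4):
            np.add.at(acc[b], starts, attr_row[:L, b])
    if n_seq == 0:
        raise ValueError("no sequences")
    return pd.DataFrame(acc / n_seq, index=list(bases),
                        columns=pd.RangeIndex(1, n_bins + 1, name="bin"))
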