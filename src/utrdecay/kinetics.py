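"""Half-life estimation from metabolic-labeling conversion time courses.

Input is the already background-subtracted, chase-normalized T>C conversion
fraction per gene, condition and chase timepoint. Each series is fit to a
single-exponential decay v(t) = v0 * exp(-lambda * t) by nonlinear least
squares; the half-life is ln2 / lambda. Genes are retained only when the
fit converges with R^2 above a gate in every condition, and ranked by the
between-condition change in half-life to define stability classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LAMBDA_BOUNDS = (1e-6, 100.0)  # per hour


@dataclass
class ConversionSeries:
    gene_id: str
    condition: str
    timepoints: np.ndarray  # hours, strictly increasing, includes 0
    values: np.ndarray      # normalized conversion fraction, >= 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints) != len(self.values):
            raise ValueError("timepoints and values must align")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must include 0")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and >= 0")


@dataclass
class HalfLifeFit:
    gene_id: str
    condition: str
    decay_rate: float   # lambda, per hour
    halflife: float     # ln2 / lambda, hours
    r_squared: float
    converged: bool


def _exp_decay(t, v0, lam):
    return v0 * np.exp(-lam * t)


def fit_halflife(series: ConversionSeries) -> HalfLifeFit:
    """Nonlinear least-squares fit of a single-exponential decay.

    v0 is free (initialized at the first observation), lambda is
    initialized at ln2 / median timepoint and bounded in (1e-6, 100) /h.
    ``converged`` is False when the optimizer fails, the data are all zero,
    or lambda pins to its lower bound (no measurable decay).
    """
    t, v = series.timepoints, series.values
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints to fit a decay")
    failed = HalfLifeFit(series.gene_id, series.condition,
                         np.nan, np.nan, np.nan, False)
    if np.all(v == 0):
        return failed
    lam0 = np.log(2) / max(np.median(t), 1e-3)
    lam0 = float(np.clip(lam0, *LAMBDA_BOUNDS))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_decay, t, v, p0=[max(v[0], 1e-9), lam0],
                bounds=([0.0, LAMBDA_BOUNDS[0]], [np.inf, LAMBDA_BOUNDS[1]]),
                maxfev=10000)
    except (RuntimeError, ValueError):
        return failed
    v0, lam = float(popt[0]), float(popt[1])
    if lam <= LAMBDA_BOUNDS[0] * 1.01:
        return failed  # flat series: lambda collapsed onto the bound
    resid = v - _exp_decay(t, v0, lam)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-18 else np.nan)
    if not np.isfinite(r2):
        return failed
    return HalfLifeFit(series.gene_id, series.condition, lam,
                       float(np.log(2) / lam), r2, True)


def fit_all(table: pd.DataFrame) -> list[HalfLifeFit]:
    """Fit every (gene, condition) series in a long-format conversion table
    with columns gene, condition, timepoint_h, value."""
    fits = []
    for (gene, cond), grp in table.groupby(["gene", "condition"], sort=True):
        grp = grp.sort_values("timepoint_h")
        series = ConversionSeries(gene, cond,
                                  grp["timepoint_h"].to_numpy(),
                                  grp["value"].to_numpy())
        fits.append(fit_halflife(series))
    return fits


def filter_fits(fits: list[HalfLifeFit], r2_min: float = 0.6) -> set[str]:
    """Genes whose fits converge with R^2 > r2_min in EVERY condition."""
    by_gene: dict[str, list[HalfLifeFit]] = {}
    for f in fits:
        by_gene.setdefault(f.gene_id, []).append(f)
    if not by_gene:
        return set()
    n_cond = max(len(v) for v in by_gene.values())
    return {g for g, fs in by_gene.items()
            if len(fs) == n_cond and all(f.converged and f.r_squared > r2_min
                                         for f in fs)}


@dataclass
class StabilityClasses:
    delta_halflife: pd.Series  # condition B - condition A, hours, per gene
    labels: pd.Series          # {decreased, increased} over 2*n_top genes
    n_top: int


def rank_delta_halflife(fits_a: list[HalfLifeFit], fits_b: list[HalfLifeFit],
                        n_top: int, genes: set[str] | None = None
                        ) -> StabilityClasses:
    """Label the n_top most-decreased and most-increased genes by
    delta half-life (B - A). Ties break lexicographically on gene id."""
    ha = {f.gene_id: f.halflife for f in fits_a if f.converged}
    hb = {f.gene_id: f.halflife for f in fits_b if f.converged}
    common = sorted(set(ha) & set(hb) & (genes if genes is not None else set(ha)))
    delta = pd.Series({g: hb[g] - ha[g] for g in common}, dtype=float)
    if 2 * n_top > len(delta):
        warnings.warn(f"requested 2*{n_top} labels but only {len(delta)} genes "
                      "available; labeling all", stacklevel=2)
        n_top = len(delta) // 2 + len(delta) % 2
    order = sorted(delta.index, key=lambda g: (delta[g], g))
    decreased = order[:n_top]
    increased = order[-n_top:][::-1] if n_top else []
    labels = pd.Series({**{g: "decreased" for g in decreased},
                        **{g: "increased" for g in increased}}, dtype=object)
    return StabilityClasses(delta, labels, n_top)


def fits_to_frame(fits: list[HalfLifeFit]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": f.gene_id, "condition": f.condition,
                          "halflife_h": f.halflife, "r2": f.r_squared,
                          "converged": f.converged} for f in fits])
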