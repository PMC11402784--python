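"""End-to-end recovery benchmarks on the synthetic study conditions.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages and measures how well the known planted signal is
recovered. They back both the acceptance script and the acceptance test
suite. Problem sizes are the package's desk-scale study conditions:
1,000 genes for half-life recovery, 2,000 sequences for the sequence
model, the default 300-gene transcriptome for metaprofiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import clip, features, kinetics, motifs
from .core import CrosslinkTrack, UtrRecord
from .simulate import (KMER_FAMILIES, SimConfig, attach_expression,
                       generate_transcriptome, make_kmer_family_ranks,
                       simulate_crosslinks, simulate_expression_and_de,
                       simulate_slamseq)

SLAM_TIMEPOINTS = [0, 3, 6, 12, 24, 48]  # hours of chase


def _sub(seed: int, k: int) -> int:
    return (seed * 7919 + k) % (2 ** 31)


# --------------------------------------------------- 1. half-life recovery

def halflife_recovery(seed: int = 0, n_genes: int = 1000) -> dict:
    """Median relative half-life error and down-regulon label recovery on
    the default conversion noise (sd 0.02) and destabilization (2x)."""
    cfg = SimConfig(n_genes=n_genes, seed=_sub(seed, 1))
    _, truth = generate_transcriptome(cfg)
    table = simulate_slamseq(truth, SLAM_TIMEPOINTS, cfg)
    fits = kinetics.fit_all(table)
    rel_err = [abs(f.halflife - truth.halflife[f.gene_id][f.condition])
               / truth.halflife[f.gene_id][f.condition]
               for f in fits if f.converged]
    kept = kinetics.filter_fits(fits)
    by_cond = {c: [f for f in fits if f.condition == c]
               for c in ("naive", "primed")}
    down = {g for g, c in truth.classes.items() if c == "down"}
    classes = kinetics.rank_delta_halflife(by_cond["naive"], by_cond["primed"],
                                           n_top=len(down), genes=kept)
    recovered = down & set(classes.labels[classes.labels == "decreased"].index)
    return {"median_rel_error_pct": 100.0 * float(np.median(rel_err)),
            "label_recovery_pct": 100.0 * len(recovered) / len(down),
            "n": n_genes}


# --------------------------------------------- 3. k-mer family clustering

def kmer_clustering_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    hits = 0
    want = frozenset(frozenset(v) for v in KMER_FAMILIES.values())
    for i in range(n_seeds):
        df = make_kmer_family_ranks(seed=_sub(seed, 100 + i))
        kmers = list(df["kmer"])
        combined = motifs.combine_distances(
            motifs.rank_distance_matrix(df["rank"].to_numpy()),
            motifs.jaccard_matrix(kmers))
        groups = motifs.cluster_kmers(combined, kmers, n_clusters=3)
        hits += frozenset(frozenset(g.kmers) for g in groups) == want
    return {"family_recovery_pct": 100.0 * hits / n_seeds,
            "jaccard_uga_ugg": motifs.substring_jaccard_distance("UGA", "UGG"),
            "n": n_seeds}


# --------------------------------------------------------- 4. GBM harness

def _one_signal_matrix(n_rows: int, seed: int):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.where(rng.random(n_rows) < 0.5, "decreased", "increased"),
                  index=[f"r{i:04d}" for i in range(n_rows)])
    X = pd.DataFrame(rng.normal(size=(n_rows, 6)),
                     columns=[f"noise_{j}" for j in range(6)], index=y.index)
    X["signal"] = np.where(y == "increased", 1.0, 0.0) + rng.normal(0, 0.05,
                                                                    n_rows)
    return X, y


def gbm_benchmark(seed: int = 0, n_separable: int = 400,
                  n_null: int = 1000) -> dict:
    """Hold-out AUROC on a separable one-signal matrix, the label-permuted
    null, and the importance rank of the informative column."""
    X, y = _one_signal_matrix(n_separable, _sub(seed, 2))
    model, ev = features.train_stability_classifier(X, y,
                                                    split_seed=_sub(seed, 3))
    y_test = (y.loc[ev.test_index] == "increased").to_numpy()
    influence, perm = features.feature_importance(model, X.loc[ev.test_index],
                                                  y_test, seed=_sub(seed, 4))
    Xn, yn = _one_signal_matrix(n_null, _sub(seed, 5))
    rng = np.random.default_rng(_sub(seed, 6))
    yn = pd.Series(rng.permutation(yn.to_numpy()), index=yn.index)
    _, ev_null = features.train_stability_classifier(Xn, yn,
                                                     split_seed=_sub(seed, 7))
    return {"separable_holdout_auroc": ev.auroc,
            "label_permuted_auroc": ev_null.auroc,
            "signal_rank_influence": int(influence.rank(ascending=False)["signal"]),
            "signal_rank_permutation": int(perm.rank(ascending=False)["signal"]),
            "n": n_separable}


# ------------------------------------------- 5. planted-signal metaprofile

def planted_metaprofile(seed: int = 0, window: int = 100,
                        n_boot: int = 1000) -> dict:
    """Mean normalized regulator coverage in the 100 nt upstream of the PAS
    for down- vs control-class 3'UTRs in the primed condition, with
    bootstrap 95% CIs over regions."""
    cfg = SimConfig(seed=_sub(seed, 8))  # default study conditions
    records, truth = generate_transcriptome(cfg)
    track = simulate_crosslinks(records, truth, "primed", cfg)
    tpm, _ = simulate_expression_and_de(truth, cfg)
    attach_expression(records, tpm)
    expr = {r.gene_id: r.tpm["primed"] for r in records}
    out = {}
    rng = np.random.default_rng(_sub(seed, 9))
    for cls_label in ("down", "control"):
        recs = [r for r in records if r.regulation_class == cls_label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = clip.metaprofile(track, recs, clip.pas_anchors(recs),
                                    (-window, 0), expr, n_boot=n_boot,
                                    seed=_sub(seed, 9))
        per_region = np.nanmean(prof.region_matrix, axis=1)
        boots = per_region[rng.integers(0, len(per_region),
                                        size=(n_boot, len(per_region)))].mean(axis=1)
        out[cls_label] = {"mean": float(per_region.mean()),
                          "ci_lo": float(np.percentile(boots, 2.5)),
                          "ci_hi": float(np.percentile(boots, 97.5))}
    return {"down_mean": out["down"]["mean"],
            "control_mean": out["control"]["mean"],
            "down_ci_lo": out["down"]["ci_lo"],
            "control_ci_hi": out["control"]["ci_hi"],
            "ratio": out["down"]["mean"] / out["control"]["mean"],
            "ci_disjoint": out["down"]["ci_lo"] > out["control"]["ci_hi"],
            "n": cfg.n_genes}


# ------------------------------------------------------- 6. sequence model

def seqmodel_benchmark(seed: int = 0, n_genes: int = 3000,
                       include_null: bool = True) -> dict:
    """CNN+GRU on the planted terminal-AUU task (2,000 down/up sequences):
    test AUROC, the label-shuffled null, and the planted-position
    attribution contrast."""
    from . import seqmodel as sm

    cfg = SimConfig(n_genes=n_genes, seed=_sub(seed, 10),
                    utr_length_range=(150, 300))
    records, truth = generate_transcriptome(cfg)
    sel = [r for r in records if r.regulation_class in ("down", "up")]
    seqs = {r.gene_id: r.sequence for r in sel}
    labels = {r.gene_id: r.regulation_class for r in sel}
    ds = sm.encode_and_split(seqs, labels, seed=_sub(seed, 11))
    model, metrics = sm.build_and_train(ds, sm.ArchConfig(seed=_sub(seed, 12)))

    mask = ds.split == "test"
    X = ds.X[mask]
    ids = [g for g, m in zip(ds.ids, mask) if m]
    attr = sm.attribute(model, X, target_class="down", n_steps=24)
    rho = sm.completeness_correlation(model, X, attr, "down")
    scores = np.abs(attr.sum(axis=2))
    at_motif, background = [], []
    for i, g in enumerate(ids):
        planted = set()
        for p in truth.motif_positions[g]:
            planted.update(range(p, p + 3))
        for j in range(len(seqs[g])):
            (at_motif if j in planted else background).append(scores[i, j])
    result = {"test_auroc": metrics["auroc"],
              "test_accuracy": metrics["accuracy"],
              "attr_planted_mean": float(np.mean(at_motif)),
              "attr_background_mean": float(np.mean(background)),
              "attr_planted_to_background_ratio":
                  float(np.mean(at_motif) / np.mean(background)),
              "completeness_rho": float(rho),
              "n": len(seqs)}
    if include_null:
        rng = np.random.default_rng(_sub(seed, 13))
        vals = list(labels.values())
        rng.shuffle(vals)
        ds_null = sm.encode_and_split(seqs, dict(zip(labels, vals)),
                                      seed=_sub(seed, 11))
        _, null_metrics = sm.build_and_train(ds_null,
                                             sm.ArchConfig(seed=_sub(seed, 14)))
        result["label_shuffled_auroc"] = null_metrics["auroc"]
    return result


# ---------------------------------------------------- 7. filter bookkeeping

def regulation_group_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Six-row DE toy covering each classification branch."""
    de = pd.DataFrame({
        "gene_id": ["down_ok", "up_ok", "ctrl_ok", "low_tpm", "short_utr",
                    "ambiguous"],
        "log2FC": [-1.0, 1.2, 0.1, -1.0, -2.0, -0.7],
        "padj": [0.001, 0.004, 0.5, 0.001, 0.01, 0.2]})
    ann = pd.DataFrame({"gene_id": de["gene_id"],
                        "utr_length": [500, 400, 300, 500, 80, 600],
                        "biotype": ["protein_coding"] * 6})
    tpm = pd.DataFrame({"gene_id": de["gene_id"],
                        "tpm_a": [10.0, 8.0, 6.0, 2.0, 9.0, 7.0],
                        "tpm_b": [9.0, 7.0, 5.5, 1.0, 8.0, 6.0]})
    return de, ann, tpm


def abundance_fixture() -> tuple[list[UtrRecord], CrosslinkTrack, dict]:
    """Five UTRs engineered so exactly two survive the terminal-abundance
    filters (length >= 800, TPM >= 1, >= 5 cDNAs in both windows)."""
    records = [UtrRecord("short", "C" * 700),
               UtrRecord("lowtpm", "C" * 900),
               UtrRecord("sparse", "C" * 900),
               UtrRecord("ok1", "C" * 900, regulation_class="down"),
               UtrRecord("ok2", "C" * 1000, regulation_class="down")]
    track = CrosslinkTrack("s")
    for rec in records:
        vec = np.zeros(rec.width, dtype=int)
        if rec.gene_id == "sparse":
            vec[0] = 4
            vec[-300:] = 1
        else:
            vec[:300] = 1
            vec[-300:] = 2
        track.set_gene(rec.gene_id, vec)
    expr = {"short": 5.0, "lowtpm": 0.5, "sparse": 5.0, "ok1": 5.0, "ok2": 8.0}
    return records, track, expr


def filter_bookkeeping() -> dict:
    de, ann, tpm = regulation_group_fixture()
    groups = features.assign_regulation_groups(de, ann, tpm)
    counts = groups.value_counts().to_dict()
    records, track, expr = abundance_fixture()
    table, tally = clip.terminal_abundance([track], records, expr)
    return {"de_fixture_down": counts.get("down", 0),
            "de_fixture_up": counts.get("up", 0),
            "de_fixture_control": counts.get("control", 0),
            "de_fixture_excluded": counts.get("excluded", 0),
            "abundance_fixture_survivors": int(tally["kept"]),
            "n": 6}
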