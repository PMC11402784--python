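"""End-to-end orchestration: simulate -> half-lives -> regulation groups ->
features/GBM -> motif groups -> metaprofiles -> sequence model -> report.

A YAML config (validated against a strict schema: unknown keys are
rejected) drives stage toggles and per-stage parameters. One global seed
fans out to fixed per-stage seeds, so disabling one stage does not shift
another stage's randomness. Every stage writes a manifest recording its
parameters, seed, input-file hashes and outputs; the report collates the
stage metrics, each traceable to a manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clip, features, io as udio, kinetics, motifs
from .simulate import (CONDITIONS, SimConfig, attach_expression,
                       generate_transcriptome, simulate_crosslinks,
                       simulate_expression_and_de, simulate_slamseq)

STAGES = ("simulate", "slamseq", "regulation_groups", "gbm", "motifs",
          "clip", "seqmodel")
_STAGE_SEED_OFFSET = {s: 100 + i for i, s in enumerate(STAGES)}

_DEFAULT_PARAMS: dict[str, dict] = {
    "slamseq": {"timepoints": [0, 3, 6, 12, 24, 48], "r2_min": 0.6, "n_top": 30},
    "regulation_groups": {"min_utr_length": 100, "min_tpm": 5.0},
    "gbm": {"grid": "reduced", "cv_folds": 5, "cv_repeats": 5},
    "motifs": {"k": 5, "n_shuffle": 100, "n_clusters": 4, "top_n": 40,
               "merge_g_rich": False},
    "clip": {"pas_span": [-200, 50], "min_length_pas": 300,
             "terminal_min_length": 500, "n_boot": 1000},
    "seqmodel": {"max_epochs": 10, "patience": 3, "conv_filters": 8,
                 "gru_hidden": 12, "dense_units": 12},
}


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    params: dict[str, dict] = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + _STAGE_SEED_OFFSET[stage]) % (2 ** 31)

    def stage_params(self, stage: str) -> dict:
        merged = dict(_DEFAULT_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged


def validate_config(path: str | Path) -> list[str]:
    """Validate a YAML pipeline config; returns a list of errors (empty =
    valid). Unknown keys anywhere are errors; no stage runs on failure."""
    try:
        raw = udio.read_yaml(path)
    except Exception as exc:  # unparseable file -> single fatal error
        return [f"cannot parse config: {exc}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    errors: list[str] = []
    known = {"out_dir", "seed", "sim", "stages", "params"}
    for key in set(raw) - known:
        errors.append(f"unknown top-level key: {key}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed: must be an integer")
    if "sim" in raw:
        try:
            SimConfig.from_dict(raw["sim"]).validate()
        except (ValueError, TypeError) as exc:
            errors.append(f"sim: {exc}")
    for stage, on in (raw.get("stages") or {}).items():
        if stage not in STAGES:
            errors.append(f"unknown stage key: {stage}")
        elif not isinstance(on, bool):
            errors.append(f"stages.{stage}: must be a boolean")
    for stage, block in (raw.get("params") or {}).items():
        if stage not in STAGES:
            errors.append(f"params for unknown stage: {stage}")
        elif not isinstance(block, dict):
            errors.append(f"params.{stage}: must be a mapping")
        else:
            for key in set(block) - set(_DEFAULT_PARAMS.get(stage, {})):
                errors.append(f"params.{stage}: unknown parameter {key}")
    return errors


def load_config(path: str | Path) -> PipelineConfig:
    errors = validate_config(path)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    raw = udio.read_yaml(path)
    cfg = PipelineConfig(
        out_dir=raw.get("out_dir", "results/pipeline"),
        seed=raw.get("seed", 0),
        sim=SimConfig.from_dict(raw.get("sim", {})),
        params=raw.get("params", {}))
    cfg.stages.update(raw.get("stages", {}))
    return cfg


# ----------------------------------------------------------------- runner

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, stage: str, params: dict, seed: int,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage, "seed": seed, "params": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


class MissingUpstreamError(RuntimeError):
    def __init__(self, stage: str, missing: str):
        super().__init__(
            f"stage '{stage}' needs missing upstream output '{missing}'; "
            "enable the producing stage or point the config at existing files")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "skipped": []}
    ctx: dict = {}

    for stage in STAGES:
        if not config.stages.get(stage, False):
            report["skipped"].append(stage)
            continue
        runner = _STAGE_RUNNERS[stage]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = runner(config, ctx, out)
        report["stages"][stage] = metrics
    if report["skipped"]:
        report["note"] = ("stages skipped by configuration: "
                          + ", ".join(report["skipped"]))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ------------------------------------------------------------ stage bodies

def _stage_simulate(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    sim = config.sim
    records, truth = generate_transcriptome(sim)
    tracks = {c: simulate_crosslinks(records, truth, c, sim) for c in CONDITIONS}
    slam = simulate_slamseq(truth, config.stage_params("slamseq")["timepoints"], sim)
    tpm, de = simulate_expression_and_de(truth, sim)
    attach_expression(records, tpm)
    paths = []
    fasta = out / "utrs.fasta"
    udio.write_fasta(records, fasta, seed=sim.seed)
    paths.append(fasta)
    for cond, tr in tracks.items():
        p = out / f"crosslinks_{cond}.bed"
        udio.write_crosslink_bed(tr, p, seed=sim.seed)
        paths.append(p)
    for name, df in [("slamseq.tsv", slam), ("tpm.tsv", tpm), ("de.tsv", de),
                     ("annotation.tsv", udio.records_to_annotation(records))]:
        udio.write_table(df, out / name, seed=sim.seed)
        paths.append(out / name)
    truth.write(out / "truth.tsv", seed=sim.seed)
    paths.append(out / "truth.tsv")
    ctx.update(records=records, truth=truth, tracks=tracks, slam=slam,
               tpm=tpm, de=de)
    _write_manifest(out, "simulate", sim.to_dict(), sim.seed, [], paths)
    return {"n_genes": len(records),
            "library_sizes": {c: t.library_size for c, t in tracks.items()}}


def _stage_slamseq(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    if "slam" not in ctx:
        raise MissingUpstreamError("slamseq", "simulate.slamseq table")
    params = config.stage_params("slamseq")
    fits = kinetics.fit_all(ctx["slam"])
    kept = kinetics.filter_fits(fits, params["r2_min"])
    by_cond = {c: [f for f in fits if f.condition == c] for c in CONDITIONS}
    classes = kinetics.rank_delta_halflife(by_cond["naive"], by_cond["primed"],
                                           params["n_top"], genes=kept)
    fit_path = out / "halflives.tsv"
    udio.write_table(kinetics.fits_to_frame(fits), fit_path, seed=config.stage_seed("slamseq"))
    cls_df = pd.DataFrame({"gene": classes.labels.index,
                           "delta_h": classes.delta_halflife[classes.labels.index].values,
                           "label": classes.labels.values})
    cls_path = out / "stability_classes.tsv"
    udio.write_table(cls_df, cls_path, seed=config.stage_seed("slamseq"))
    ctx.update(fits=fits, kept_genes=kept, stability=classes)
    _write_manifest(out, "slamseq", params, config.stage_seed("slamseq"),
                    [out / "slamseq.tsv"], [fit_path, cls_path])
    truth = ctx["truth"]
    down = {g for g, c in truth.classes.items() if c == "down"}
    recovered = len(down & set(classes.labels[classes.labels == "decreased"].index))
    return {"n_fit": len(fits), "n_kept": len(kept),
            "down_recovery": recovered / max(len(down), 1)}


def _stage_regulation_groups(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    for need in ("de", "tpm", "records"):
        if need not in ctx:
            raise MissingUpstreamError("regulation_groups", f"simulate.{need}")
    params = config.stage_params("regulation_groups")
    ann = udio.records_to_annotation(ctx["records"])
    groups = features.assign_regulation_groups(
        ctx["de"], ann, ctx["tpm"], min_utr_length=params["min_utr_length"],
        min_tpm=params["min_tpm"])
    path = out / "regulation_groups.tsv"
    udio.write_table(groups.rename_axis("gene_id").reset_index(), path,
                     seed=config.stage_seed("regulation_groups"))
    ctx["regulation_groups"] = groups
    _write_manifest(out, "regulation_groups", params,
                    config.stage_seed("regulation_groups"),
                    [out / "de.tsv", out / "tpm.tsv", out / "annotation.tsv"],
                    [path])
    return {"counts": groups.value_counts().to_dict()}


def _stage_gbm(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    if "stability" not in ctx:
        raise MissingUpstreamError("gbm", "slamseq.stability_classes")
    params = config.stage_params("gbm")
    records = ctx["records"]
    labels = ctx["stability"].labels
    subset = [r for r in records if r.gene_id in labels.index]
    simple = features.compute_simple_features(subset)
    track_cols = [features.aggregate_track_features(t, subset)
                  for t in ctx["tracks"].values()]
    X = features.build_feature_matrix(simple, track_cols)
    y = labels.loc[X.index]
    model, ev = features.train_stability_classifier(
        X, y, split_seed=config.stage_seed("gbm"), grid=params["grid"],
        cv_folds=params["cv_folds"], cv_repeats=params["cv_repeats"])
    influence, perm = features.feature_importance(
        model, X.loc[ev.test_index], (y.loc[ev.test_index] == "increased").to_numpy(),
        seed=config.stage_seed("gbm"))
    card = {"grid": params["grid"], "best_params": ev.best_params,
            "cv_auroc": ev.cv_auroc, "holdout": {"auroc": ev.auroc,
                                                 "accuracy": ev.accuracy,
                                                 "mcc": ev.mcc},
            "relative_influence": influence.sort_values(ascending=False).head(10).to_dict(),
            "permutation_importance": perm.sort_values(ascending=False).head(10).to_dict()}
    path = out / "gbm_model_card.json"
    path.write_text(json.dumps(card, indent=2, sort_keys=True) + "\n")
    _write_manifest(out, "gbm", params, config.stage_seed("gbm"),
                    [out / "stability_classes.tsv"], [path])
    return card["holdout"]


def _stage_motifs(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    if "tracks" not in ctx:
        raise MissingUpstreamError("motifs", "simulate.crosslink tracks")
    params = config.stage_params("motifs")
    seqs = {r.gene_id: r.sequence for r in ctx["records"]}
    stats = motifs.kmer_enrichment(ctx["tracks"]["primed"], seqs, k=params["k"],
                                   n_shuffle=params["n_shuffle"],
                                   seed=config.stage_seed("motifs"))
    top = stats.table.head(params["top_n"])
    kmers = list(top["kmer"])
    combined = motifs.combine_distances(
        motifs.rank_distance_matrix(top["rank"].to_numpy()),
        motifs.jaccard_matrix(kmers))
    groups = motifs.cluster_kmers(combined, kmers, params["n_clusters"],
                                  merge_g_rich=params["merge_g_rich"],
                                  provenance=f"pipeline_seed{config.seed}")
    stats_path = out / "kmer_stats.tsv"
    tbl = stats.table.copy()
    tbl["relevant_offsets"] = tbl["kmer"].map(
        lambda k: ",".join(map(str, stats.relevant_positions.get(k, []))))
    udio.write_table(tbl, stats_path, seed=config.stage_seed("motifs"))
    groups_path = out / "motif_groups.json"
    groups_path.write_text(json.dumps(
        [{"name": g.name, "kmers": g.kmers} for g in groups], indent=2) + "\n")
    ctx.update(kmer_stats=stats, motif_groups=groups)
    _write_manifest(out, "motifs", params, config.stage_seed("motifs"),
                    [out / "crosslinks_primed.bed"], [stats_path, groups_path])
    return {"top_kmer": kmers[0],
            "groups": {g.name: len(g.kmers) for g in groups}}


def _stage_clip(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    if "tracks" not in ctx:
        raise MissingUpstreamError("clip", "simulate.crosslink tracks")
    params = config.stage_params("clip")
    records = ctx["records"]
    expr = {r.gene_id: r.tpm.get("primed", 0.0) for r in records}
    outputs = []
    metrics = {}
    span = tuple(params["pas_span"])
    for cls_label in ("down", "control"):
        recs = [r for r in records if r.regulation_class == cls_label]
        prof = clip.metaprofile(
            ctx["tracks"]["primed"], recs, clip.pas_anchors(recs), span, expr,
            anchor_name="pas", min_length=params["min_length_pas"],
            n_boot=params["n_boot"], seed=config.stage_seed("clip"))
        p = out / f"metaprofile_pas_{cls_label}.tsv"
        udio.write_table(prof.to_frame(), p, seed=config.stage_seed("clip"))
        outputs.append(p)
        window = (prof.offsets >= -100) & (prof.offsets < 0)
        metrics[f"mean_terminal_coverage_{cls_label}"] = float(
            np.nanmean(prof.mean[window]))
    lfc = clip.binned_log2fc(ctx["tracks"]["naive"], ctx["tracks"]["primed"],
                             records, span=params["terminal_min_length"])
    p = out / "binned_log2fc.tsv"
    udio.write_table(lfc, p, seed=config.stage_seed("clip"))
    outputs.append(p)
    _write_manifest(out, "clip", params, config.stage_seed("clip"),
                    [out / f"crosslinks_{c}.bed" for c in CONDITIONS], outputs)
    return metrics


def _stage_seqmodel(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    from . import seqmodel as sm

    if "records" not in ctx:
        raise MissingUpstreamError("seqmodel", "simulate.records")
    params = config.stage_params("seqmodel")
    seqs, labels = {}, {}
    for r in ctx["records"]:
        if r.regulation_class in ("down", "up"):
            seqs[r.gene_id] = r.sequence
            labels[r.gene_id] = r.regulation_class
    ds = sm.encode_and_split(seqs, labels, seed=config.stage_seed("seqmodel"))
    cfg = sm.ArchConfig(seed=config.stage_seed("seqmodel"),
                        max_epochs=params["max_epochs"],
                        patience=params["patience"],
                        conv_filters=params["conv_filters"],
                        gru_hidden=params["gru_hidden"],
                        dense_units=params["dense_units"])
    model, metrics = sm.build_and_train(ds, cfg)
    path = out / "seqmodel_metrics.json"
    path.write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    ctx["seqmodel"] = model
    _write_manifest(out, "seqmodel", params, config.stage_seed("seqmodel"),
                    [out / "utrs.fasta"], [path])
    return {k: metrics[k] for k in ("accuracy", "auroc", "n")}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "slamseq": _stage_slamseq,
    "regulation_groups": _stage_regulation_groups,
    "gbm": _stage_gbm,
    "motifs": _stage_motifs,
    "clip": _stage_clip,
    "seqmodel": _stage_seqmodel,
}
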