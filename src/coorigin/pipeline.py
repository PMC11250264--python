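"""End-to-end orchestration with a reproducibility manifest.

Stages run in dependency order (simulate -> windows -> filter/count -> atac
-> predict -> stats -> evaluate); every output is hashed into a manifest
along with the stage's configuration, so an unchanged rerun can skip
up-to-date stages and a changed one invalidates downstream outputs.
All interchange between stages is plain TSV for auditability.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atac import AccessibilityMatrix, AtacConfig, CellAnnotation, aggregate_fragments, equalize, read_fragments
from .model import CooModelConfig, CooPrediction, predict_cohort, predictions_to_frame
from .simulate import CohortSpec, SimConfig, write_sim_outputs
from .stats import DiffWindowConfig, compare_tmb, diff_windows, origin_contingency
from .variants import (ClonalFilterConfig, MutationMatrix, build_mutation_matrix,
                       clonal_filter, compute_tmb, normalize_rows, read_somatic_vcf)
from .windows import GenomeLayout, IntervalTrack, WindowFilterConfig, WindowSet, build_windows

__all__ = ["RunConfig", "run_end_to_end", "evaluate_against_truth"]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig | None = None
    window_filter: WindowFilterConfig = field(default_factory=WindowFilterConfig)
    clonal_filter: ClonalFilterConfig = field(default_factory=ClonalFilterConfig)
    atac: AtacConfig = field(default_factory=AtacConfig)
    model: CooModelConfig = field(default_factory=CooModelConfig)
    diff_windows: DiffWindowConfig = field(default_factory=DiffWindowConfig)
    # external inputs; filled in automatically when sim is configured
    sizes: str | None = None
    mappability: str | None = None
    gaps: str | None = None
    vcf_dir: str | None = None
    cohorts: str | None = None
    fragments: str | None = None
    barcodes: str | None = None
    classes: str | None = None
    truth: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if "sim" in raw:
            sim_raw = dict(raw.pop("sim") or {})
            if "cohort_spec" in sim_raw:
                sim_raw["cohort_spec"] = tuple(
                    CohortSpec(c["label"], int(c["n_tumors"]), dict(c["origin_mixture"]))
                    for c in sim_raw["cohort_spec"]
                )
            if "cell_types" in sim_raw:
                sim_raw["cell_types"] = tuple(sim_raw["cell_types"])
            sim = SimConfig(**sim_raw)
        sections = {
            "window_filter": WindowFilterConfig,
            "clonal_filter": ClonalFilterConfig,
            "atac": AtacConfig,
            "model": CooModelConfig,
            "diff_windows": DiffWindowConfig,
        }
        kwargs = {}
        for key, typ in sections.items():
            if key in raw:
                kwargs[key] = typ(**(raw.pop(key) or {}))
        kwargs.update(raw)
        cfg = cls(sim=sim, **kwargs)
        if cfg.sim is not None:
            cfg.sim = _replace_seed(cfg.sim, cfg.seed)
        return cfg


def _replace_seed(sim: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


class _Manifest:
    """Stage signatures and output hashes, persisted as JSON."""

    def __init__(self, path: str):
        self.path = path
        self.data: dict = {"stages": {}, "version": __version__}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)
            self.data.setdefault("stages", {})

    def up_to_date(self, stage: str, signature: str, outputs: list[str]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or rec.get("signature") != signature:
            return False
        for out in outputs:
            if not os.path.exists(out) or _sha256(out) != rec["outputs"].get(out):
                return False
        return True

    def record(self, stage: str, signature: str, outputs: list[str]) -> None:
        self.data["stages"][stage] = {
            "signature": signature,
            "outputs": {out: _sha256(out) for out in outputs},
        }
        self.save()

    def invalidate_from(self, stage: str, order: list[str]) -> None:
        if stage not in order:
            return
        for later in order[order.index(stage):]:
            self.data["stages"].pop(later, None)

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


_STAGE_ORDER = ["sim", "windows", "filter_count", "atac", "predict", "stats", "evaluate"]


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute all stages, skipping those whose inputs and config are unchanged.

    Returns the manifest dictionary. Any stage failure propagates with the
    failing stage named; its outputs are not recorded as up to date.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = _Manifest(os.path.join(cfg.outdir, "manifest.json"))
    j = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731

    def run_stage(stage, signature, outputs, fn):
        if manifest.up_to_date(stage, signature, outputs):
            return False
        manifest.invalidate_from(stage, _STAGE_ORDER)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, signature, outputs)
        return True

    # ---- sim ------------------------------------------------------------
    if cfg.sim is not None:
        sim_dir = j("sim")
        sig = _config_hash({"sim": asdict(cfg.sim)})
        sim_outputs = [os.path.join(sim_dir, n) for n in
                       ("sizes.tsv", "mappability.bed", "gaps.bed", "fragments.tsv",
                        "barcodes.tsv", "classes.tsv", "cohorts.tsv", "truth.tsv")]
        run_stage("sim", sig, sim_outputs, lambda: write_sim_outputs(cfg.sim, sim_dir))
        cfg.sizes = os.path.join(sim_dir, "sizes.tsv")
        cfg.mappability = os.path.join(sim_dir, "mappability.bed")
        cfg.gaps = os.path.join(sim_dir, "gaps.bed")
        cfg.vcf_dir = os.path.join(sim_dir, "vcf")
        cfg.cohorts = os.path.join(sim_dir, "cohorts.tsv")
        cfg.fragments = os.path.join(sim_dir, "fragments.tsv")
        cfg.barcodes = os.path.join(sim_dir, "barcodes.tsv")
        cfg.classes = os.path.join(sim_dir, "classes.tsv")
        cfg.truth = os.path.join(sim_dir, "truth.tsv")

    for name in ("sizes", "mappability", "gaps", "vcf_dir", "cohorts",
                 "fragments", "barcodes", "classes"):
        if getattr(cfg, name) is None:
            raise ValueError(f"run config missing input {name!r} and no sim section")

    # ---- windows ---------------------------------------------------------
    windows_bed, exclusions = j("windows.bed"), j("exclusions.tsv")
    sig = _config_hash({
        "cfg": asdict(cfg.window_filter),
        "inputs": [_sha256(p) for p in (cfg.sizes, cfg.mappability, cfg.gaps)],
    })

    def _windows():
        layout = GenomeLayout.from_tsv(cfg.sizes)
        ws = build_windows(layout, IntervalTrack.from_bed(cfg.mappability),
                           IntervalTrack.from_bed(cfg.gaps), cfg.window_filter)
        ws.to_bed(windows_bed)
        ws.exclusions_tsv(exclusions)

    run_stage("windows", sig, [windows_bed, exclusions], _windows)
    windows = WindowSet.from_bed(windows_bed, cfg.window_filter.window_size)
    layout = GenomeLayout.from_tsv(cfg.sizes)
    windows.chromosomes = frozenset(layout.names)

    # ---- filter/count ----------------------------------------------------
    vcfs = sorted(glob.glob(os.path.join(cfg.vcf_dir, "*.vcf")) +
                  glob.glob(os.path.join(cfg.vcf_dir, "*.vcf.gz")))
    matrix_tsv, filter_tsv = j("matrix.tsv"), j("filter_report.tsv")
    sig = _config_hash({
        "cfg": asdict(cfg.clonal_filter),
        "windows": _sha256(windows_bed),
        "vcfs": [_sha256(p) for p in vcfs],
    })

    def _filter_count():
        results = [clonal_filter(read_somatic_vcf(p), cfg.clonal_filter) for p in vcfs]
        mm = build_mutation_matrix(results, windows)
        mm.to_tsv(matrix_tsv)
        pd.DataFrame([{
            "tumor": r.tumor_id, "mean_vaf": r.mean_vaf, "sd_vaf": r.sd_vaf,
            "threshold": r.threshold, "n_input": r.n_input,
            "n_retained": r.n_retained, "retained_fraction": r.retained_fraction,
            "tmb": compute_tmb(r),
        } for r in results]).to_csv(filter_tsv, sep="\t", index=False)

    run_stage("filter_count", sig, [matrix_tsv, filter_tsv], _filter_count)

    # ---- atac --------------------------------------------------------------
    features_tsv, raw_tsv = j("features.tsv"), j("features_raw.tsv")
    sig = _config_hash({
        "cfg": asdict(cfg.atac),
        "windows": _sha256(windows_bed),
        "inputs": [_sha256(p) for p in (cfg.fragments, cfg.barcodes, cfg.classes)],
    })

    def _atac():
        ann = CellAnnotation.from_tsv(cfg.barcodes, cfg.classes)
        raw, _ = aggregate_fragments(read_fragments(cfg.fragments), ann, windows)
        equalize(raw, cfg.atac).to_tsv(features_tsv, raw_tsv)

    run_stage("atac", sig, [features_tsv, raw_tsv], _atac)

    # ---- predict -----------------------------------------------------------
    pred_tsv, model_json = j("predictions.tsv"), j("model_config.json")
    sig = _config_hash({
        "cfg": asdict(cfg.model),
        "inputs": [_sha256(matrix_tsv), _sha256(features_tsv)],
    })

    def _predict():
        mm = MutationMatrix.from_tsv(matrix_tsv)
        X = AccessibilityMatrix.from_tsv(features_tsv).equalized
        preds = predict_cohort(normalize_rows(mm), X, cfg.model)
        predictions_to_frame(preds).to_csv(pred_tsv, sep="\t")
        with open(model_json, "w") as fh:
            json.dump(asdict(cfg.model), fh, indent=2, sort_keys=True)

    run_stage("predict", sig, [pred_tsv, model_json], _predict)

    # ---- stats --------------------------------------------------------------
    diff_tsv, tmb_tsv, cont_json = j("diff_windows.tsv"), j("tmb.tsv"), j("contingency.json")
    sig = _config_hash({
        "cfg": asdict(cfg.diff_windows), "seed": cfg.seed,
        "inputs": [_sha256(matrix_tsv), _sha256(pred_tsv), _sha256(cfg.cohorts),
                   _sha256(filter_tsv)],
    })

    def _stats():
        labels = pd.read_csv(cfg.cohorts, sep="\t", index_col="tumor")["cohort"]
        mm = MutationMatrix.from_tsv(matrix_tsv)
        diff_windows(normalize_rows(mm), labels, cfg.diff_windows).to_csv(
            diff_tsv, sep="\t", index_label="window")
        filt = pd.read_csv(filter_tsv, sep="\t", index_col="tumor")
        tmb_res = compare_tmb(filt["tmb"], labels)
        pd.DataFrame([asdict(tmb_res)]).to_csv(tmb_tsv, sep="\t", index=False)
        preds = _load_predictions(pred_tsv)
        summary = origin_contingency(preds, labels, seed=cfg.seed)
        with open(cont_json, "w") as fh:
            json.dump({
                "table": {c: summary.table[c].to_dict() for c in summary.table.columns},
                "p": summary.result.p, "method": summary.result.method,
                "se": summary.result.se, "seed": summary.result.seed,
            }, fh, indent=2, sort_keys=True)

    run_stage("stats", sig, [diff_tsv, tmb_tsv, cont_json], _stats)

    # ---- evaluate -------------------------------------------------------------
    if cfg.truth is not None:
        eval_json = j("evaluation.json")
        sig = _config_hash({"inputs": [_sha256(pred_tsv), _sha256(cfg.truth)]})

        def _evaluate():
            pred_df = pd.read_csv(pred_tsv, sep="\t", index_col="tumor")
            truth = pd.read_csv(cfg.truth, sep="\t", index_col="tumor")["true_origin"]
            report = evaluate_against_truth(pred_df, truth)
            with open(eval_json, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)

        run_stage("evaluate", sig, [eval_json], _evaluate)

    manifest.data["config"] = _config_hash({
        k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
        for k, v in vars(cfg).items() if v is not None
    })
    manifest.save()
    return manifest.data


def _load_predictions(pred_tsv: str) -> list[CooPrediction]:
    df = pd.read_csv(pred_tsv, sep="\t", index_col="tumor")
    imp_cols = [c for c in df.columns if c.startswith("imp_")]
    preds = []
    for tumor, row in df.iterrows():
        imp = pd.Series({c[4:]: row[c] for c in imp_cols})
        origin = None if row["abstained"] else row["origin"]
        preds.append(CooPrediction(str(tumor), origin, imp, abstained=bool(row["abstained"])))
    return preds


def evaluate_against_truth(predictions, truth: pd.Series) -> dict:
    """Accuracy report of predicted origins against a ground-truth table.

    `predictions` is either a list of CooPrediction or the predictions
    DataFrame (index tumor, columns origin/abstained). Tumor ids must match
    the truth table exactly.
    """
    if isinstance(predictions, pd.DataFrame):
        pred = predictions[["origin", "abstained"]].copy()
    else:
        pred = pd.DataFrame(
            {"origin": [p.origin for p in predictions],
             "abstained": [p.abstained for p in predictions]},
            index=pd.Index([p.tumor_id for p in predictions], name="tumor"),
        )
    pred.index = pred.index.astype(str)
    truth = truth.copy()
    truth.index = truth.index.astype(str)
    if set(pred.index) != set(truth.index):
        missing = set(truth.index) ^ set(pred.index)
        raise ValueError(f"tumor id mismatch between predictions and truth: {sorted(missing)[:5]}")
    truth = truth.reindex(pred.index)
    called = ~pred["abstained"].astype(bool)
    correct = (pred.loc[called, "origin"] == truth[called])
    confusion = pd.crosstab(truth[called], pred.loc[called, "origin"])
    per_origin = {}
    for origin in sorted(truth.unique()):
        mask = called & (truth == origin)
        per_origin[origin] = float((pred.loc[mask, "origin"] == origin).mean()) if mask.any() else None
    return {
        "n": int(len(pred)),
        "n_called": int(called.sum()),
        "abstention_rate": float((~called).mean()),
        "accuracy": float(correct.mean()) if called.any() else None,
        "per_origin_accuracy": per_origin,
        "confusion": {str(t): {str(p): int(v) for p, v in row.items() if v}
                      for t, row in confusion.iterrows()},
    }
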