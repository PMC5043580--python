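"""End-to-end orchestration: peaks + genome + PWM library -> reports.

The pipeline runs the four-step workflow: partition the labeled data into
train/test, build the matched random background and the per-kb feature
matrices, train the L1 path with cross-validation, select the penalty
(1-s.e. or knowledge-based anchor retention), then evaluate on the withheld
test set and derive co-occurrence / candidate-cofactor reports.  Every
stage's outputs are plain files (JSON/TSV/BED) so stages are independently
inspectable, and all floats are serialized at 12 significant digits so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cooccurrence import anchor_exclusive_fraction, binarize, cooccurrence_matrix, rank_candidates
from .features import (
    Featurizer,
    background_from_sequences,
    normalize_per_kb,
    stack_labeled,
    train_test_split,
)
from .intervals import generate_random_peaks, read_bed, write_bed
from .models import (
    confusion,
    fdr,
    fit_lasso_path,
    model_at,
    ppv,
    predict,
    roc_auc,
    select_lambda_1se,
    select_lambda_knowledge,
    sensitivity,
    specificity,
)
from .motifs import read_pwm_library

log = logging.getLogger("motifgrammar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    peaks: Path
    genome: Path
    pwms: Path
    allowed: Path
    outdir: Path
    seed: int
    anchors: tuple[str, ...] = ()
    rule: str = "1se"  # or "knowledge"
    threshold: float = 6.0
    split_fraction: float = 0.75
    n_folds: int = 10
    cutoff: float = 0.5
    pwm_format: str | None = None

    def validate(self) -> None:
        for p in (self.peaks, self.genome, self.pwms, self.allowed):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")
        if self.rule not in ("1se", "knowledge"):
            raise ValueError("selection rule must be '1se' or 'knowledge'")
        if self.rule == "knowledge" and not self.anchors:
            raise ValueError("knowledge-based selection needs at least one anchor motif id")


def _round_sig(x, digits: int = 12):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return x
        return float(f"{x:.{digits}g}")
    if isinstance(x, dict):
        return {k: _round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, digits) for v in x]
    if isinstance(x, (np.floating,)):
        return _round_sig(float(x), digits)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round_sig(x.tolist(), digits)
    return x


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_sig(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def model_from_json(path: str | Path):
    """Rehydrate a sparse lasso model written by the pipeline's model.json."""
    from .models import FittedModel

    with open(path) as fh:
        d = json.load(fh)
    motif_ids = d["motif_ids"]
    coef = np.zeros(len(motif_ids))
    for m, c in d["active_features"].items():
        coef[motif_ids.index(m)] = c
    return FittedModel(
        kind="lasso",
        motif_ids=motif_ids,
        hyperparams={"lambda": d["selected_lambda"], "seed": d.get("seed")},
        active_features=d["active_features"],
        coef=coef,
        intercept=d["intercept"],
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("motifgrammar %s seed=%d", __version__, config.seed)
        cfg_echo = {k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()}
        write_json(cfg_echo, outdir / "config.json")

        stage = "load"
        try:
            peaks = read_bed(config.peaks, name="positive")
            allowed = read_bed(config.allowed, name="allowed")
            pwms = read_pwm_library(config.pwms, format=config.pwm_format)
            known = {p.id for p in pwms}
            missing = [a for a in config.anchors if a not in known]
            if missing:
                raise KeyError(f"anchor id(s) not in the PWM library: {missing}")
            log.info("%d peaks, %d allowed regions, %d PWMs", len(peaks), len(allowed), len(pwms))
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "background"
        try:
            background_peaks = generate_random_peaks(
                peaks, allowed, seed=config.seed, name="background"
            )
            write_bed(background_peaks, outdir / "background.bed")
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "scan"
        try:
            from .intervals import extract_sequences

            pos_seqs = extract_sequences(peaks, config.genome)
            bg_seqs = extract_sequences(background_peaks, config.genome)
            bg_model = background_from_sequences({**pos_seqs, **bg_seqs})
            featurizer = Featurizer(
                pwms=pwms,
                background=bg_model,
                threshold=config.threshold,
                genome=config.genome,
            )
            from .features import count_matrix

            pos_counts = count_matrix(peaks, pos_seqs, pwms, bg_model, config.threshold)
            bg_counts = count_matrix(
                background_peaks, bg_seqs, pwms, bg_model, config.threshold
            )
            counts = stack_labeled(pos_counts, bg_counts)
            counts.to_tsv(outdir / "counts.tsv")
            lengths = peaks.lengths() + background_peaks.lengths()
            features = normalize_per_kb(counts, lengths)
            features.to_tsv(outdir / "features.tsv")
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "train"
        try:
            split = train_test_split(features, config.split_fraction, config.seed)
            train = features.subset_rows(split.train_indices)
            test = features.subset_rows(split.test_indices)
            path = fit_lasso_path(train, n_folds=config.n_folds, seed=config.seed)
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "select"
        try:
            lam_1se = select_lambda_1se(path)
            lam_know = (
                select_lambda_knowledge(path, list(config.anchors))
                if config.anchors
                else None
            )
            lam = lam_know if config.rule == "knowledge" else lam_1se
            model = model_at(path, lam)
            write_json(
                {
                    "lambda_grid": path.lambdas,
                    "cv_auc_mean": path.cv_auc_mean,
                    "cv_auc_se": path.cv_auc_se,
                    "lambda_1se": lam_1se,
                    "lambda_knowledge": lam_know,
                    "rule": config.rule,
                    "selected_lambda": lam,
                    "n_folds": config.n_folds,
                    "seed": config.seed,
                    "active_features": model.active_features,
                    "intercept": model.intercept,
                    "motif_ids": model.motif_ids,
                },
                outdir / "model.json",
            )
            log.info(
                "rule=%s lambda=%.6g model size=%d", config.rule, lam, model.size
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "evaluate"
        try:
            scores = predict(model, test)
            cm = confusion(scores, test.labels, cutoff=config.cutoff)
            roc = roc_auc(scores, test.labels)
            metrics = {
                "auc": roc.auc,
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
                "ppv": ppv(cm),
                "fdr": fdr(cm),
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "cutoff": config.cutoff,
                "n_test": cm.total,
                "model_size": model.size,
                "lambda": lam,
                "seed": config.seed,
            }
            write_json(metrics, outdir / "metrics.json")
            pd.DataFrame(
                {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
            ).to_csv(outdir / "roc.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc)

        stage = "cooccurrence"
        try:
            presence = binarize(pos_counts)
            active = [m for m in model.active_features if m in presence.motif_ids]
            if active:
                cooccurrence_matrix(presence, active).to_tsv(outdir / "cooccurrence.tsv")
            if config.anchors:
                excl = anchor_exclusive_fraction(presence, config.anchors[0])
                excl.to_tsv(outdir / "anchor_exclusive.tsv")
                rank_candidates(model, excl).to_csv(
                    outdir / "candidates.tsv", sep="\t", index=False
                )
        except Exception as exc:
            raise PipelineError(stage, exc)

        log.info("run complete: %s", outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
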