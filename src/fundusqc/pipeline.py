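"""End-to-end orchestration: simulate -> assess -> score -> threshold ->
enhance -> evaluate, plus the ROP raw-vs-enhanced diagnosis demo.

Every stage is a plain library function over the module APIs; the CLI in
:mod:`fundusqc.cli` is a thin wrapper around these. All randomness funnels
through one master seed, fanned out per stage by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .assessment import ClassicalBackend, assess
from .enhancement import EnhancementParams, enhance
from .evalstats import binary_metrics, delong_test, roc_auc, two_proportion_z
from .ranking import (
    consensus_ranking,
    rank_items,
    run_tournament,
    simulated_rater,
    spearman_rank_corr,
)
from .scoring import ThresholdPair, classify_grade, compute_iqcs, grid_search_thresholds
from .synthetic import Stratum, ValidationError, generate_dataset

# fixed per-stage offsets applied to the master seed
SEED_OFFSETS = {
    "simulate": 11, "train": 23, "rank": 37, "rop": 53, "eval": 71,
}


@dataclass
class PipelineConfig:
    """Round-trippable run configuration; unknown keys are rejected."""

    out_dir: str = "out"
    backend: str = "classical"           # 'classical' or 'tiny_cnn'
    checkpoint: str | None = None
    thresholds: tuple[float, float] | str = (0.2, 0.8)  # or "fit"
    image_size: int = 96
    seed: int = 0
    n_per_stratum: int = 25

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = (json.load(fh) if path.suffix == ".json"
                    else yaml.safe_load(fh))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("thresholds"), list):
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh)


def default_strata(n: int = 25) -> list[Stratum]:
    """The standard mixed study population: clean and defective images of
    both locations spanning the three quality grades."""
    return [
        Stratum("post_clean", n, "posterior"),
        Stratum("post_dark_macula", n, "posterior",
                illumination_strength=(0.45, 0.7), illumination_region="macula"),
        Stratum("post_blur", n, "posterior", blur_sigma=(1.6, 2.6)),
        Stratum("peri_clean", n, "peripheral"),
        Stratum("peri_dark", n, "peripheral",
                illumination_strength=(0.45, 0.7), illumination_region="whole"),
        Stratum("peri_blur", n, "peripheral", blur_sigma=(1.6, 2.6)),
        Stratum("peri_cut", n, "peripheral",
                integrity_missing_frac=(0.18, 0.28)),
        Stratum("peri_severe", n, "peripheral",
                illumination_strength=(0.92, 1.0), illumination_region="whole"),
    ]


def _get_backend(config: PipelineConfig):
    if config.backend == "classical":
        return ClassicalBackend()
    if config.backend == "tiny_cnn":
        if not config.checkpoint:
            raise ValidationError(
                "tiny_cnn backend needs a checkpoint directory; train one "
                "with cmd_train or the 'fundusqc train' command"
            )
        return nn.CNNBackend.load(config.checkpoint)
    raise ValidationError(f"unknown backend {config.backend!r}")


def cmd_simulate(config: PipelineConfig, strata: list[Stratum] | None = None):
    """Generate the synthetic dataset and write images + manifest."""
    strata = strata or default_strata(config.n_per_stratum)
    out = Path(config.out_dir) / "images"
    records, manifest = generate_dataset(
        strata, seed=config.seed + SEED_OFFSETS["simulate"], out_dir=out,
        width=config.image_size, height=config.image_size,
    )
    summary = manifest.groupby(["location", "grade"]).size().to_dict()
    return records, manifest, {str(k): int(v) for k, v in summary.items()}


def cmd_train(config: PipelineConfig, records, **cfg_overrides):
    """Train the tiny CNN backend on generated records; save a checkpoint."""
    tc = nn.desk_scale_config(seed=config.seed + SEED_OFFSETS["train"],
                              **cfg_overrides)
    backend = nn.train_cnn_backend(records, tc)
    ckpt = Path(config.out_dir) / "checkpoints"
    backend.save(ckpt)
    return backend, str(ckpt)


def cmd_run_all(config: PipelineConfig,
                strata: list[Stratum] | None = None) -> dict:
    """Full pass: simulate, assess, score, grade, enhance; write reports.

    Returns the aggregate report (grade counts, mean +/- SD IQCS before and
    after enhancement) and writes the per-image CSV plus enhanced PNGs.
    """
    import imageio.v3 as iio

    records, manifest, sim_summary = cmd_simulate(config, strata)
    backend = _get_backend(config)
    out_dir = Path(config.out_dir)
    (out_dir / "enhanced").mkdir(parents=True, exist_ok=True)

    if config.thresholds == "fit":
        scores, grades = [], []
        for rec in records:
            probs = assess(rec.image, backend,
                           location_override=rec.image.location)
            scores.append(compute_iqcs(probs).score)
            grades.append(rec.truth_grade)
        gs = grid_search_thresholds(scores, grades)
        t = gs.best
    else:
        t = ThresholdPair(*config.thresholds)

    rows = []
    for rec, (_, mrow) in zip(records, manifest.iterrows()):
        probs = assess(rec.image, backend,
                       location_override=rec.image.location)
        result = compute_iqcs(probs)
        grade = classify_grade(result.score, t)
        enhanced, report = enhance(rec.image, probs, t, backend=backend)
        if "gamma" in report.actions or "clahe" in report.actions:
            iio.imwrite(out_dir / "enhanced" / mrow["path"], enhanced.pixels)
        rows.append({
            "path": mrow["path"], "location": rec.image.location,
            "iqcs": result.score, "grade": grade,
            "truth_grade": rec.truth_grade,
            "actions": "+".join(report.actions),
            "iqcs_before": report.iqcs_before,
            "iqcs_after": report.iqcs_after,
            "rephotograph_advised": report.rephotograph_advised,
        })
    per_image = pd.DataFrame(rows)
    per_image.to_csv(out_dir / "per_image.csv", index=False)

    enhanced_mask = per_image["iqcs_after"].notna()
    after = per_image["iqcs_after"].where(enhanced_mask,
                                          per_image["iqcs_before"])
    aggregate = {
        "thresholds": {"lower": t.lower, "upper": t.upper},
        "n_images": len(per_image),
        "simulated": sim_summary,
        "grade_counts": per_image["grade"].value_counts().to_dict(),
        "n_enhanced": int(enhanced_mask.sum()),
        "n_discarded": int((per_image["actions"] == "discard_flag").sum()),
        "iqcs_before_mean": float(per_image["iqcs_before"].mean()),
        "iqcs_before_sd": float(per_image["iqcs_before"].std()),
        "iqcs_after_mean": float(after.mean()),
        "iqcs_after_sd": float(after.std()),
        "grade_accuracy": float(
            (per_image["grade"] == per_image["truth_grade"]).mean()
        ),
    }
    with open(out_dir / "aggregate.json", "w") as fh:
        json.dump(aggregate, fh, indent=2)
    return aggregate


def cmd_rank_demo(config: PipelineConfig, n_images: int = 30,
                  n_raters: int = 6, rounds: int = 15,
                  tau: float = 0.0) -> dict:
    """Ranking validation: ELO consensus ranking of a strictly
    ordered degradation series versus the IQCS ranking."""
    from .synthetic import DefectSpec, FundusSpec, apply_defects, generate_clean_fundus

    seed = config.seed + SEED_OFFSETS["rank"]
    backend = ClassicalBackend()
    strengths = np.linspace(0.0, 0.9, n_images)
    iqcs = {}
    true_quality = {}
    for i, s in enumerate(strengths):
        img = generate_clean_fundus(
            FundusSpec(width=config.image_size, height=config.image_size,
                       location="peripheral", seed=seed + i))
        rec = apply_defects(img, DefectSpec(
            illumination_strength=float(s), illumination_region="whole",
            blur_sigma=float(2.5 * s)))
        probs = assess(rec.image, backend, location_override="peripheral")
        iqcs[i] = compute_iqcs(probs).score
        true_quality[i] = -float(s)          # less degraded = higher quality
    states = []
    for r in range(n_raters):
        comp = simulated_rater(true_quality, tau=tau, seed=seed + 1000 + r)
        states.append(run_tournament(list(range(n_images)), comp,
                                     rounds=rounds, seed=seed + 2000 + r))
    consensus = consensus_ranking(states)
    rho = spearman_rank_corr(rank_items(iqcs), consensus)
    return {"n_images": n_images, "n_raters": n_raters, "rounds": rounds,
            "spearman_rho": rho}


ASPECT_DEFECTS: dict[str, tuple[str, dict]] = {
    "illumination_macula": ("posterior", dict(
        illumination_strength=(0.5, 0.9), illumination_region="macula")),
    "illumination_optic_disc": ("posterior", dict(
        illumination_strength=(0.5, 0.9), illumination_region="optic_disc")),
    "illumination_remaining": ("posterior", dict(
        illumination_strength=(0.5, 0.9), illumination_region="remaining")),
    "clarity_macula": ("posterior", dict(blur_sigma=(2.0, 4.0))),
    "clarity_optic_disc": ("posterior", dict(blur_sigma=(2.0, 4.0))),
    "clarity_remaining": ("posterior", dict(blur_sigma=(2.0, 4.0))),
    "integrity": ("peripheral", dict(integrity_missing_frac=(0.2, 0.5))),
    "illumination": ("peripheral", dict(
        illumination_strength=(0.5, 0.9), illumination_region="whole")),
    "clarity": ("peripheral", dict(blur_sigma=(2.0, 4.0))),
}


def cmd_head_benchmark(config: PipelineConfig,
                       aspects: list[str] | None = None,
                       n_train_per_class: int = 100,
                       n_test_per_class: int = 50,
                       seeds: tuple[int, ...] = (0, 1, 2),
                       image_size: int = 64) -> dict:
    """Per-aspect discriminability of the tiny CNN backend.

    For each quality aspect, trains one binary head per seed on a balanced
    clean-vs-defective dataset (one model per task, as in the reference
    design) and reports the held-out AUC, per seed and averaged.
    """
    aspects = aspects or list(ASPECT_DEFECTS)
    out: dict[str, dict] = {}
    for aspect in aspects:
        loc, kw = ASPECT_DEFECTS[aspect]
        aucs = []
        for s in seeds:
            seed = config.seed + SEED_OFFSETS["train"] + 1000 * s
            tr_strata = [Stratum("clean", n_train_per_class, loc),
                         Stratum("defect", n_train_per_class, loc, **kw)]
            te_strata = [Stratum("clean", n_test_per_class, loc),
                         Stratum("defect", n_test_per_class, loc, **kw)]
            tr, _ = generate_dataset(tr_strata, seed=seed,
                                     width=image_size, height=image_size)
            te, _ = generate_dataset(te_strata, seed=seed + 1,
                                     width=image_size, height=image_size)
            cfg = nn.desk_scale_config(seed=seed)
            x = nn._prepare([r.image for r in tr], cfg.input_size)
            y = np.array([1.0 if r.truth_labels[aspect] == "poor" else 0.0
                          for r in tr])
            head = nn.train_head(x, y, aspect, cfg)
            xt = nn._prepare([r.image for r in te], cfg.input_size)
            yt = np.array([1 if r.truth_labels[aspect] == "poor" else 0
                           for r in te])
            logit, _ = nn._forward(head.params, xt)
            aucs.append(roc_auc(nn._sigmoid(logit), yt).estimate)
        out[aspect] = {"auc_per_seed": aucs,
                       "auc_mean": float(np.mean(aucs))}
    return out


def rop_strata(n_per_class: int) -> list[Stratum]:
    """Degraded ROP-vs-normal peripheral cohort for the enhancement demo:
    every image darkened into the eligible band so the ridge is hard to see
    on raw pixels."""
    degrade = dict(illumination_strength=(0.5, 0.7),
                   illumination_region="whole")
    return [
        Stratum("normal", n_per_class, "peripheral", **degrade),
        Stratum("rop_ridge", n_per_class, "peripheral", rop_stage="ridge",
                **degrade),
    ]


def cmd_rop_demo(config: PipelineConfig, n_per_class: int = 60,
                 n_seeds: int = 3, epochs: int = 10) -> dict:
    """Raw-vs-enhanced ROP diagnosis comparison.

    Trains two identical tiny classifiers with fixed hyperparameters — one
    on raw degraded images, one on the same images after enhancement — and
    compares held-out AUC/sensitivity/specificity/accuracy with the DeLong
    and two-proportion z tests, averaged over ``n_seeds`` seeds.
    """
    backend = ClassicalBackend()
    t = (ThresholdPair(*config.thresholds)
         if config.thresholds != "fit" else ThresholdPair(0.2, 0.8))
    arm_aucs: dict[str, list[float]] = {"raw": [], "enhanced": []}
    per_seed = []
    for s in range(n_seeds):
        seed = config.seed + SEED_OFFSETS["rop"] + 101 * s
        train_recs, _ = generate_dataset(
            rop_strata(n_per_class), seed=seed,
            width=config.image_size, height=config.image_size)
        test_recs, _ = generate_dataset(
            rop_strata(n_per_class), seed=seed + 1,
            width=config.image_size, height=config.image_size)

        def enhanced_images(recs):
            out = []
            for r in recs:
                probs = assess(r.image, backend,
                               location_override="peripheral")
                img, _ = enhance(r.image, probs, t, backend=backend)
                out.append(img)
            return out

        arms = {
            "raw": ([r.image for r in train_recs],
                    [r.image for r in test_recs]),
            "enhanced": (enhanced_images(train_recs),
                         enhanced_images(test_recs)),
        }
        y_tr = np.array([1.0 if r.rop_label == "ROP" else 0.0
                         for r in train_recs])
        y_te = np.array([1 if r.rop_label == "ROP" else 0
                         for r in test_recs])
        cfg = nn.desk_scale_config(seed=seed, epochs=epochs)
        seed_row = {"seed": s}
        scores = {}
        for arm, (tr_imgs, te_imgs) in arms.items():
            x_tr = nn._prepare(tr_imgs, cfg.input_size)
            x_te = nn._prepare(te_imgs, cfg.input_size)
            head = nn.train_head(x_tr, y_tr, f"rop_{arm}", cfg)
            logit, _ = nn._forward(head.params, x_te)
            p = nn._sigmoid(logit)
            scores[arm] = p
            auc = roc_auc(p, y_te)
            metrics = binary_metrics(y_te, (p >= 0.5).astype(int))
            seed_row[arm] = {
                "auc": auc.estimate,
                "sensitivity": metrics.sensitivity.estimate,
                "specificity": metrics.specificity.estimate,
                "accuracy": metrics.accuracy.estimate,
            }
            arm_aucs[arm].append(auc.estimate)
        _, _, p_delong = delong_test(scores["enhanced"], scores["raw"], y_te)
        acc_e = seed_row["enhanced"]["accuracy"]
        acc_r = seed_row["raw"]["accuracy"]
        n = len(y_te)
        _, p_acc = two_proportion_z(round(acc_e * n), n, round(acc_r * n), n)
        seed_row["delong_p"] = p_delong
        seed_row["accuracy_z_p"] = p_acc
        per_seed.append(seed_row)
    return {
        "n_per_class": n_per_class,
        "n_seeds": n_seeds,
        "mean_auc_raw": float(np.mean(arm_aucs["raw"])),
        "mean_auc_enhanced": float(np.mean(arm_aucs["enhanced"])),
        "per_seed": per_seed,
    }
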