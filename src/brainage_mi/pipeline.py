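"""End-to-end orchestration: simulate -> train -> predict/correct ->
decode MI -> subgroup -> summary.

Stages communicate only through documented file formats (CSV tables,
JSON results, a model directory), so each stage is also runnable
standalone from the CLI on artifacts of a prior stage. A single master
seed expands deterministically into per-stage seeds, and the resolved
configuration (with its hash) is written next to every run's artifacts;
re-running an identical configuration reproduces every JSON artifact
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .age_model import (
    DEFAULT_C_GRID,
    DEFAULT_EPSILON,
    apply_bias_correction,
    evaluate,
    fit_brain_age_model,
    predict_age,
)
from .mi import mi_profile
from .schema import (
    FeatureTable,
    RegionSchema,
    ValidationError,
    load_feature_table,
    write_results,
)
from .subgroup import subgroup_report
from .synthetic import default_aging_preset, simulate_cohort

log = logging.getLogger("brainage_mi")

__all__ = ["RunConfig", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "run"
    # inputs: either simulate (preset) or load from paths
    simulate: bool = True
    n_train: int = 600
    n_test: int = 550
    train_path: str | None = None
    test_path: str | None = None
    schema_path: str | None = None
    # model
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    epsilon: float = DEFAULT_EPSILON
    bias_mode: str = "out_of_fold"
    # MI decoding
    k: int = 3
    uncorrected_mi: bool = True
    combine_volumes: bool = False
    run_subgroup: bool = True
    # seeding
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            for p in (self.train_path, self.test_path):
                if p is None or not Path(p).exists():
                    raise ValidationError(f"input table not found: {p}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")

    def stage_seeds(self) -> dict[str, int]:
        """Expand the master seed into independent per-stage seeds (< 2^31)."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("simulate_train", "simulate_test", "folds", "jitter")
        return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["c_grid"] = list(self.c_grid)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "c_grid" in d:
            d["c_grid"] = tuple(d["c_grid"])
        return cls(**d)

    def content_hash(self) -> str:
        """Hash of the scientific configuration; where artifacts land
        (out_dir) does not change what is computed."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.content_hash(), "seeds": config.stage_seeds()}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    seeds = config.stage_seeds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    resolved = {**config.to_dict(), "config_hash": config.content_hash(),
                "stage_seeds": seeds}
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )

    schema = (
        RegionSchema.from_yaml(config.schema_path)
        if config.schema_path
        else RegionSchema()
    )

    t0 = time.time()
    if config.simulate:
        preset = default_aging_preset(schema, seed=seeds["simulate_train"])
        train, truth = simulate_cohort(
            preset, schema, n=config.n_train, seed=seeds["simulate_train"]
        )
        test, _ = simulate_cohort(
            preset, schema, n=config.n_test, seed=seeds["simulate_test"]
        )
        train.to_csv(out / "cohort_train.csv")
        test.to_csv(out / "cohort_test.csv")
        truth.write(out / "truth.json")
        log.info("simulate: train %d x %d, test %d x %d (%.1fs)",
                 train.n_subjects, schema.n_features, test.n_subjects,
                 schema.n_features, time.time() - t0)
    else:
        train = load_feature_table(config.train_path, schema)
        test = load_feature_table(config.test_path, schema)

    t0 = time.time()
    model = fit_brain_age_model(
        train,
        schema,
        c_grid=config.c_grid,
        epsilon=config.epsilon,
        seed=seeds["folds"],
        bias_mode=config.bias_mode,
    )
    model.save(out / "model")
    log.info("train: selected C=%g (%.1fs)", model.C, time.time() - t0)

    # training-set metrics on the same predictions the bias fit used
    train_pred = model.oof_train_predictions
    train_corr = apply_bias_correction(train_pred, train.ages, model.bias)
    test_pred = predict_age(model, test)
    test_corr = apply_bias_correction(test_pred, test.ages, model.bias)

    metrics = {
        "selected_C": model.C,
        "bias": model.bias.to_dict(),
        "train": {
            "n": train.n_subjects,
            "before_correction": evaluate(train_pred, train.ages).to_dict(),
            "after_correction": evaluate(train_corr, train.ages).to_dict(),
        },
        "test": {
            "n": test.n_subjects,
            "before_correction": evaluate(test_pred, test.ages).to_dict(),
            "after_correction": evaluate(test_corr, test.ages).to_dict(),
        },
        "provenance": _provenance(config),
    }
    write_results(metrics, out / "metrics.json")

    preds = pd.DataFrame(
        {
            "subject_id": test.subject_ids,
            "age": test.ages,
            "predicted": test_pred,
            "corrected": test_corr,
        }
    )
    preds.to_csv(out / "predictions.csv", index=False)

    t0 = time.time()
    profile = mi_profile(
        test, test_corr, schema, k=config.k, seed=seeds["jitter"],
        combine_volumes=config.combine_volumes,
    )
    write_results(
        {**profile.to_dict(), "provenance": _provenance(config)},
        out / "mi_profile.json",
    )
    if config.uncorrected_mi:
        profile_unc = mi_profile(
            test, test_pred, schema, k=config.k, seed=seeds["jitter"],
            combine_volumes=config.combine_volumes,
        )
        write_results(
            {**profile_unc.to_dict(), "provenance": _provenance(config)},
            out / "mi_profile_uncorrected.json",
        )
    log.info("decode-mi: %d features (%.1fs)", schema.n_features, time.time() - t0)

    if config.run_subgroup:
        t0 = time.time()
        comparison = subgroup_report(test, model, k=config.k, seed=seeds["jitter"])
        write_results(
            {**comparison.to_dict(), "provenance": _provenance(config)},
            out / "subgroup.json",
        )
        log.info("subgroup: %s (%.1fs)",
                 {g: n for g, n in comparison.n_subjects.items()},
                 time.time() - t0)

    (out / "summary.md").write_text(summarize(out))
    return out


def _fmt_metrics(block: dict) -> str:
    lines = ["| set | phase | MAE (y) | RMSE (y) | R2 |", "|---|---|---|---|---|"]
    for split in ("train", "test"):
        for phase in ("before_correction", "after_correction"):
            m = block[split][phase]
            r2 = "n/a" if m["r2"] is None else f"{m['r2']:.3f}"
            lines.append(
                f"| {split} | {phase.replace('_', ' ')} | "
                f"{m['mae']:.2f} | {m['rmse']:.2f} | {r2} |"
            )
    return "\n".join(lines)


def summarize(run_dir: str | Path) -> str:
    """Human-readable report over a completed run directory."""
    run_dir = Path(run_dir)
    required = ["config_resolved.yaml", "metrics.json", "mi_profile.json"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise ValidationError(f"incomplete run; missing artifacts: {missing}")

    cfg = yaml.safe_load((run_dir / "config_resolved.yaml").read_text())
    metrics = json.loads((run_dir / "metrics.json").read_text())
    profile = json.loads((run_dir / "mi_profile.json").read_text())

    n_features = len(profile["feature_mi"])
    regions = list(next(iter(profile["region_measure"].values())).keys())

    parts = [
        "# Brain-age MI decoding run summary",
        "",
        f"- config hash: `{cfg['config_hash']}` (master seed {cfg['seed']})",
        f"- features: {n_features} over {len(regions)} regions",
        f"- selected C: {metrics['selected_C']}",
        f"- bias coefficients: alpha={metrics['bias']['alpha']:.3f}, "
        f"beta={metrics['bias']['beta']:.3f} years",
        "",
        "## Model performance",
        "",
        _fmt_metrics(metrics),
        "",
        "## MI totals (nats)",
        "",
        f"- overall total (corrected brain age): {profile['total']:.2f}",
    ]
    unc_path = run_dir / "mi_profile_uncorrected.json"
    if unc_path.exists():
        unc = json.loads(unc_path.read_text())
        parts.append(
            f"- overall total (uncorrected brain age): {unc['total']:.2f}"
        )
    for m, t in profile["measure_totals"].items():
        parts.append(f"- {m}: {t:.2f}")
    for c, t in profile["combination_totals"].items():
        parts.append(f"- {c}: {t:.2f}")

    parts += ["", "## Top-10 regions"]
    for key, top in profile["top_regions"].items():
        vals = profile["region_measure"].get(key) or profile["combinations"][key]
        ranked = ", ".join(f"{r} ({vals[r]:.3f})" for r in top)
        parts += ["", f"### {key}", "", ranked]

    sub_path = run_dir / "subgroup.json"
    if sub_path.exists():
        sub = json.loads(sub_path.read_text())
        parts += [
            "",
            "## Sex subgroups",
            "",
            f"- n: {sub['n_subjects']}",
            f"- MI totals: "
            + ", ".join(f"{g}={t:.2f}" for g, t in sub["totals"].items()),
            "",
            "| comparison | key | rho | p |",
            "|---|---|---|---|",
        ]
        for pair, block in sub["comparisons"].items():
            for key, v in block.items():
                parts.append(
                    f"| {pair} | {key} | {v['rho']:.3f} | {v['p']:.2e} |"
                )

    return "\n".join(parts) + "\n"
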