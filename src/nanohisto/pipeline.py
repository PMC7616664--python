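"""End-to-end orchestration: generate -> quantify -> correlate -> boost -> score.

``run_all`` executes the whole in-silico analogue of the biomarker study on
synthetic data with known ground truth, persisting every intermediate as a
plain-text artifact (CSV/JSON, plus per-channel TIFFs for the images) under
one output directory.  Artifacts are a pure function of (config, seed): a
single global seed fans out to fixed per-stage child seeds, so adding a
stage never perturbs the random streams of earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gtb, histoquant, scoring, synthgen
from .scoring import ValidationError

__version__ = "0.1.0"

logger = logging.getLogger("nanohisto")

# fixed per-stage seed offsets (fan-out from the global seed)
_SEED_IMAGES = 101
_SEED_FEATURES = 211
_SEED_SCORES = 307

_CSV_KW = dict(index=False, na_rep="NA")


@dataclass
class RunConfig:
    seed: int = 1
    profiles: tuple[str, ...] = ("A431", "MLS", "CT26")
    effect_config: synthgen.EffectConfig = field(
        default_factory=synthgen.EffectConfig)
    gtb_config: gtb.GTBConfig = field(default_factory=gtb.GTBConfig)
    cutoff: int = scoring.DEFAULT_CUTOFF
    n_observers: int = 10
    n_sections: int = 3
    observer_sd: float = 0.35
    output_dir: str = "nanohisto_run"
    log_level: str = "INFO"

    def resolve_profiles(self) -> list[synthgen.TissueProfile]:
        resolved = []
        for name in self.profiles:
            if name not in synthgen.BUILTIN_PROFILES:
                raise ValidationError(
                    f"unknown tissue profile {name!r}; packaged profiles: "
                    f"{sorted(synthgen.BUILTIN_PROFILES)}")
            resolved.append(synthgen.BUILTIN_PROFILES[name])
        return resolved

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effect_config" in raw:
            raw["effect_config"] = synthgen.EffectConfig(**raw["effect_config"])
        if "gtb_config" in raw:
            raw["gtb_config"] = gtb.GTBConfig(**raw["gtb_config"])
        if "profiles" in raw:
            raw["profiles"] = tuple(raw["profiles"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (where outputs land and how
        verbosely we log do not change the results)."""
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")
        fields.pop("log_level")
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    output_dir: Path
    feature_table_path: Path
    importance: gtb.ImportanceReport
    loo: gtb.LOOResult
    confusion: scoring.ConfusionMatrix
    roc: scoring.ROCResult
    correlation_fits: pd.DataFrame
    model_ids: list[str]
    provenance: dict


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage in order; see the module docstring."""
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    profiles = cfg.resolve_profiles()  # fail fast before any compute
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate-images"
    try:
        # 1. synthetic multichannel fields + ground truth
        img_dir = out / "images"
        image_rows = []
        for i, profile in enumerate(profiles):
            image, truth = synthgen.make_tissue_image(
                profile, cfg.seed + _SEED_IMAGES + i)
            synthgen.write_image(image, truth, profile, img_dir, profile.name)
            row = histoquant.compute_feature_panel(image)
            row["sample"] = profile.name
            image_rows.append(row)
            logger.info("rendered %s: %d vessels", profile.name,
                        truth.object_count["CD31"])

        stage = "quantify"
        image_features = pd.DataFrame(image_rows)
        image_features = image_features[
            ["sample"] + list(histoquant.FEATURE_NAMES)]
        image_features.to_csv(out / "image_features.csv", **_CSV_KW)

        # 2. synthetic animal panel for the learner
        stage = "simulate-features"
        table = synthgen.make_feature_dataset(cfg.effect_config,
                                              cfg.seed + _SEED_FEATURES)
        feature_path = out / "features.csv"
        table.to_csv(feature_path, **_CSV_KW)

        # 3. per-feature accumulation trendlines
        stage = "correlate"
        fits = []
        y_all = table[synthgen.OUTCOME_COLUMN]
        for name in histoquant.FEATURE_NAMES:
            x = table[name]
            keep = x.notna()
            if keep.sum() < 3 or np.ptp(x[keep].to_numpy()) == 0:
                continue
            slope, intercept, r2 = histoquant.linear_fit(x[keep], y_all[keep])
            fits.append((name, slope, intercept, r2))
        correlation_fits = pd.DataFrame(
            fits, columns=["feature", "slope", "intercept", "r_squared"])
        correlation_fits.to_csv(out / "correlation_fits.csv", **_CSV_KW)

        # 4. gradient tree boosting: LOO predictions + importance ranking
        stage = "gtb"
        X = table[list(histoquant.FEATURE_NAMES)]
        loo = gtb.loo_cv(X, y_all.to_numpy(), cfg.gtb_config)
        loo.to_frame().to_csv(out / "loo_predictions.csv", **_CSV_KW)
        importance = gtb.feature_importance(loo.fold_models)
        importance.to_frame().to_csv(out / "importance.csv", **_CSV_KW)

        # 5. ordinal product scoring on the ten-model panel
        stage = "score"
        fixtures = synthgen.default_fixtures()
        matrix = synthgen.make_observer_scores(
            fixtures, cfg.n_observers, cfg.n_sections, cfg.observer_sd,
            cfg.seed + _SEED_SCORES)
        matrix.to_csv(out / "observer_scores.csv")
        records = scoring.product_scores(matrix)
        pd.DataFrame(
            [(r.model_id, r.vessel_score, r.tam_score, r.product)
             for r in records],
            columns=["model", "vessel_score", "tam_score", "product"],
        ).to_csv(out / "product_scores.csv", **_CSV_KW)

        truth_by_model = {f.model_id: f.truth_class for f in fixtures}
        preds = [scoring.classify(r.product, cfg.cutoff) for r in records]
        confusion = scoring.confusion(
            preds, [truth_by_model[r.model_id] for r in records])
        _write_json(out / "confusion.json", confusion.to_dict())

        # 6. ROC over pooled per-(observer, section) product scores
        stage = "roc"
        wide = matrix.scores.pivot_table(
            index=["model", "observer", "section"], columns="marker",
            values="score").reset_index()
        item_scores = (wide["vessel"] * wide["TAM"]).to_numpy()
        item_labels = wide["model"].map(truth_by_model).to_numpy()
        roc = scoring.roc(item_scores, item_labels)
        roc.to_frame().to_csv(out / "roc_points.csv", **_CSV_KW)

        stage = "report"
        report_obj = RunReport(
            output_dir=out, feature_table_path=feature_path,
            importance=importance, loo=loo, confusion=confusion, roc=roc,
            correlation_fits=correlation_fits,
            model_ids=[f.model_id for f in fixtures],
            provenance={"config_hash": cfg.digest(), "seed": cfg.seed,
                        "version": __version__},
        )
        report(report_obj)
        _write_manifest(out)
        return report_obj
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (partial outputs kept in {out})"
        ) from exc


def report(run: RunReport) -> dict:
    """Write the human-readable summary (JSON + markdown) for a finished run."""
    for attr in ("importance", "loo", "confusion", "roc"):
        if getattr(run, attr) is None:
            raise ValidationError(f"run is incomplete: missing {attr}")
    top = run.importance.ranking[:6]
    summary = {
        "provenance": run.provenance,
        "models": run.model_ids,
        "top_features": top,
        "loo_r_squared": run.loo.r_squared,
        "confusion": run.confusion.to_dict(),
        "auroc": run.roc.auroc,
    }
    _write_json(run.output_dir / "summary.json", summary)
    cm = run.confusion
    lines = [
        "# nanohisto run summary",
        "",
        f"- seed: {run.provenance['seed']}  config: {run.provenance['config_hash']}"
        f"  version: {run.provenance['version']}",
        f"- tumour models: {', '.join(run.model_ids)}",
        f"- top-ranked features (split occurrence): {', '.join(top)}",
        f"- leave-one-out R2 (squared Pearson): {run.loo.r_squared:.3f}",
        f"- confusion at product-score cutoff: tp={cm.tp} tn={cm.tn} "
        f"fp={cm.fp} fn={cm.fn} (accuracy {cm.accuracy:.2f})",
        f"- AUROC of the product score: {run.roc.auroc:.3f}",
        "",
    ]
    (run.output_dir / "summary.md").write_text("\n".join(lines))
    return summary


def load_summary(output_dir) -> dict:
    return json.loads((Path(output_dir) / "summary.json").read_text())


def _write_manifest(out: Path) -> None:
    entries = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            entries[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    _write_json(out / "manifest.json", {"artifacts": entries})
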