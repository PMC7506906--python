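"""End-to-end orchestration: simulate -> segment -> extract -> validate.

A run executes the two predictor models against the same CBMS response:

* model 1 ("itug"): subject descriptives + the 78 averaged iTUG signal
  features;
* model 2 ("clinical"): subject descriptives + the standard clinical
  tests (TUG time, habitual and fast gait speed, SPPB, 30-s chair stand,
  eight-level balance scale, short FES-I).

Both are validated with the same Monte-Carlo partitions so their RMSEP
curves can be compared pairwise.  All randomness flows from one master
seed recorded in the run manifest; rerunning with the same configuration
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ItugError, SchemaError
from .features import (
    DESCRIPTIVE_COLUMNS,
    FEATURE_MANIFEST,
    FeatureConfig,
    average_features,
    extract_features,
)
from .plsr import FeatureTable, classify_vip
from .segmentation import SegmentationConfig, segment_trial, split_repetitions
from .synthetic import simulate_cohort, simulate_session
from .validation import CvConfig, CvResult, compare_models, monte_carlo_cv

#: Clinical-test predictor columns of model 2.
CLINICAL_TEST_COLUMNS: tuple[str, ...] = (
    "tug_s", "gait_speed_habitual", "gait_speed_fast",
    "sppb", "cst30", "lbs8", "sfesi",
)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 7
    n_community: int = 40
    n_outpatient: int = 20
    noise_acc_sd: float = 0.15
    noise_gyro_sd: float = 3.0
    jitter: float = 0.04
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_iter: int = 100
    n_folds: int = 6
    alpha: float = 0.05
    a_max: int = 10
    selection_frequency_threshold: float = 0.5

    def cv_config(self) -> CvConfig:
        return CvConfig(
            n_iter=self.n_iter, n_folds=self.n_folds, alpha=self.alpha,
            a_max=self.a_max, seed=self.seed,
            selection_frequency_threshold=self.selection_frequency_threshold,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for sub, subcls in (("segmentation", SegmentationConfig),
                            ("features", FeatureConfig)):
            if sub in data:
                sd = data.pop(sub) or {}
                known = {f.name for f in dataclasses.fields(subcls)}
                bad = set(sd) - known
                if bad:
                    raise SchemaError(f"unknown {sub} config keys: {sorted(bad)}")
                if subcls is FeatureConfig and "step_band" in sd:
                    sd["step_band"] = tuple(sd["step_band"])
                kwargs[sub] = subcls(**sd)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        return cls(**data, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def extract_session_features(
    rec, seg_cfg: SegmentationConfig, feat_cfg: FeatureConfig
) -> dict[str, float]:
    """Split a session, segment and extract each repetition, and average."""
    reps = split_repetitions(rec, seg_cfg)
    vectors = []
    for rep in reps:
        seg = segment_trial(rep, seg_cfg)
        vectors.append(extract_features(rep, seg, feat_cfg))
    return average_features(vectors)


def build_feature_csv(config: RunConfig):
    """Simulate the cohort and produce the averaged per-subject features.

    Returns ``(features_df, clinical_df, cbms, truth)``; the features
    DataFrame holds the 78 averaged signal features per subject.
    """
    profiles, clinical, cbms, truth = simulate_cohort(
        config.n_community, config.n_outpatient, config.seed
    )
    rows = {}
    for i, prof in enumerate(profiles):
        try:
            rec, _ = simulate_session(
                prof, seed=config.seed + 1000 + i,
                noise_acc_sd=config.noise_acc_sd,
                noise_gyro_sd=config.noise_gyro_sd,
                jitter=config.jitter,
            )
            rows[prof.id] = extract_session_features(
                rec, config.segmentation, config.features
            )
        except ItugError as exc:
            raise ItugError(f"subject {prof.id}: {type(exc).__name__}: {exc}") from exc
    features = pd.DataFrame.from_dict(rows, orient="index")
    features = features.reindex(columns=list(FEATURE_MANIFEST))
    features.index.name = "subject_id"
    return features, clinical, cbms, truth


def _descriptives(clinical: pd.DataFrame) -> pd.DataFrame:
    d = clinical[list(DESCRIPTIVE_COLUMNS)].copy()
    d["sex"] = (d["sex"] == "M").astype(float)
    return d


def build_model_table(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    cbms: pd.Series,
    model: str,
) -> FeatureTable:
    """Assemble the predictor table for one of the two models.

    ``model`` is ``"itug"`` (descriptives + signal features) or
    ``"clinical"`` (descriptives + clinical tests).  Remaining missing
    values are imputed with the column median.
    """
    if model == "itug":
        X = pd.concat([features, _descriptives(clinical)], axis=1)
    elif model == "clinical":
        X = pd.concat([clinical[list(CLINICAL_TEST_COLUMNS)],
                       _descriptives(clinical)], axis=1)
    else:
        raise ValueError(f"unknown model {model!r}")
    X = X.apply(lambda c: c.fillna(c.median()))
    return FeatureTable(X, cbms.loc[X.index])


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def save_cv_result(out_dir: str | Path, result: CvResult) -> Path:
    """Write a harness result as plain CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a = np.arange(1, len(result.rmsep_mean) + 1)
    pd.DataFrame(
        {"components": a, "rmsep_mean": result.rmsep_mean, "rmsep_sd": result.rmsep_sd}
    ).to_csv(out / "rmsep_curve.csv", index=False)

    sel = pd.DataFrame({
        "feature": result.final_features,
        "frequency": result.selection_frequency[result.final_features].to_numpy(),
        "vip": result.final_vip.to_numpy(),
        "vip_band": classify_vip(result.final_vip.to_numpy()),
        "r2": result.univariate_r2[result.final_features].to_numpy(),
    })
    P = result.final_model.P
    for c in range(P.shape[1]):
        sel[f"loading_{c + 1}"] = P[:, c]
    sel.to_csv(out / "selected_features.csv", index=False)

    pd.DataFrame({
        "component": np.arange(1, result.chosen_a + 1),
        "explained_mean": result.explained_mean,
        "ci_lo": result.explained_ci[:, 0],
        "ci_hi": result.explained_ci[:, 1],
    }).to_csv(out / "explained_variation.csv", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "chosen_components": result.chosen_a,
                "explained_total": result.explained_total,
                "rmsep_at_chosen": float(result.rmsep_mean[result.chosen_a - 1]),
                "n_iterations_used": len(result.iterations),
                "n_skipped": result.n_skipped,
            },
            fh, indent=2,
        )

    rows = []
    for i, rec in enumerate(result.iterations):
        row = {"iteration": i, "test_idx": ";".join(map(str, rec.test_idx))}
        for j, v in enumerate(rec.rmsep_by_a, start=1):
            row[f"rmsep_a{j}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "iterations.csv", index=False)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full chain and write all outputs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features, clinical, cbms, truth = build_feature_csv(config)
    features.to_csv(out / "features.csv")
    clinical.to_csv(out / "clinical.csv")
    cbms.to_frame().to_csv(out / "cbms.csv")
    truth.theta.to_frame().to_csv(out / "theta.csv")

    results: dict[str, CvResult] = {}
    for model in ("itug", "clinical"):
        table = build_model_table(features, clinical, cbms, model)
        results[model] = monte_carlo_cv(table, config.cv_config())
        save_cv_result(out / f"model_{model}", results[model])

    comp = compare_models(results["itug"], results["clinical"])
    pd.DataFrame([{
        "z": comp.z, "p": comp.p, "mean_rmsep_difference": comp.mean_difference,
        "itug_chosen_a": results["itug"].chosen_a,
        "clinical_chosen_a": results["clinical"].chosen_a,
    }]).to_csv(out / "comparison.csv", index=False)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "config.yaml").write_text(cfg_yaml)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "n_subjects": int(len(cbms)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    (out / "report.md").write_text(report(out))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run."""
    run = Path(run_dir)
    lines = ["# iTUG pipeline run", ""]
    found = False
    for model in ("itug", "clinical"):
        mdir = run / f"model_{model}"
        if not (mdir / "summary.json").exists():
            continue
        found = True
        with open(mdir / "summary.json") as fh:
            summ = json.load(fh)
        ev = pd.read_csv(mdir / "explained_variation.csv")
        sel = pd.read_csv(mdir / "selected_features.csv")
        lines += [
            f"## Model: {model}",
            "",
            f"- chosen components: {summ['chosen_components']}",
            f"- total explained variation: {summ['explained_total']:.3f}",
            f"- RMSEP at chosen components: {summ['rmsep_at_chosen']:.2f}",
            "",
            "| component | explained | 95% CI |",
            "|---|---|---|",
        ]
        for _, r in ev.iterrows():
            lines.append(
                f"| {int(r['component'])} | {r['explained_mean']:.3f} "
                f"| {r['ci_lo']:.3f}-{r['ci_hi']:.3f} |"
            )
        lines += ["", "| feature | VIP | band | r2 |", "|---|---|---|---|"]
        for _, r in sel.sort_values("vip", ascending=False).iterrows():
            lines.append(
                f"| {r['feature']} | {r['vip']:.3f} | {r['vip_band']} | {r['r2']:.3f} |"
            )
        lines.append("")
    if not found:
        raise ItugError(f"no model outputs found under {run}")
    comp_path = run / "comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path).iloc[0]
        lines += [
            "## Model comparison (paired RMSEP)",
            "",
            f"- Z = {comp['z']:.2f}, two-sided p = {comp['p']:.2g}",
            f"- mean RMSEP difference (itug - clinical): "
            f"{comp['mean_rmsep_difference']:.3f}",
            "",
        ]
    return "\n".join(lines)
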