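"""Config-driven end-to-end orchestration with a machine-readable manifest.

A run walks: generate-or-ingest -> preprocess -> cluster -> significance
(alpha ladder) -> LOFO -> naive Bayes (optional validation cohort) ->
outcomes -> SOM mosaics, writing every stage output under the run
directory.  The manifest records per-stage parameters, seeds and sha256
checksums of inputs and outputs, so an unchanged config reproduces every
file byte-for-byte, and stages whose input checksums are unchanged are
skipped on re-run.

Every stochastic stage receives an explicit seed from the config; there is
no hidden global RNG.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ClusterAssignment, CohortTable
from .hclust import agglomerate_complete, pairwise_distance
from .lofo import lofo_table
from .nbayes import fit as nb_fit
from .nbayes import lofo_cv_accuracy, predict_table
from .outcomes import classify_cci, outcomes_from_frame, outcomes_to_frame
from .preprocess import impute_median, standardize
from .significance import qq_pairs, reference_distribution, significance_ladder
from .som import cluster_mosaic, train_som
from .synthetic import CohortSpec, generate_cohort, generate_outcomes

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    synthetic: CohortSpec | None = None
    cohort_csv: Path | None = None
    outcomes_csv: Path | None = None
    validation_csv: Path | None = None
    alpha: float = 0.004
    alpha_ladder: list[float] = field(default_factory=lambda: [0.004])
    n_reps: int = 10
    normalize_distance: bool = True
    run_lofo: bool = False
    som_rows: int | None = None
    som_cols: int | None = None
    som_epochs: int = 50

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is required")
        if self.synthetic is None and self.cohort_csv is None:
            raise ConfigError("either a synthetic spec or a cohort CSV is required")
        for a in [self.alpha, *self.alpha_ladder]:
            if not (0 < a < 1):
                raise ConfigError(f"alpha {a} outside (0,1)")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigError("config must provide a seed")
        syn = None
        if "synthetic" in raw:
            syn_raw = dict(raw["synthetic"])
            syn_raw.setdefault("seed", raw["seed"])
            syn = CohortSpec.from_dict(syn_raw)
        cfg = cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw["seed"]),
            synthetic=syn,
            cohort_csv=Path(raw["cohort_csv"]) if raw.get("cohort_csv") else None,
            outcomes_csv=Path(raw["outcomes_csv"]) if raw.get("outcomes_csv") else None,
            validation_csv=Path(raw["validation_csv"]) if raw.get("validation_csv") else None,
            alpha=float(raw.get("alpha", 0.004)),
            alpha_ladder=[float(a) for a in raw.get("alpha_ladder", [raw.get("alpha", 0.004)])],
            n_reps=int(raw.get("n_reps", 10)),
            normalize_distance=bool(raw.get("normalize_distance", True)),
            run_lofo=bool(raw.get("run_lofo", False)),
            som_rows=raw.get("som_rows"),
            som_cols=raw.get("som_cols"),
            som_epochs=int(raw.get("som_epochs", 50)),
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict[str, dict] = {}
        if path.exists():
            self.stages = json.loads(path.read_text()).get("stages", {})

    def up_to_date(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.stages.get(stage)
        return (
            rec is not None
            and rec.get("key") == key
            and all(Path(o).exists() for o in rec.get("outputs", []))
            and [str(o) for o in outputs] == rec.get("outputs", [])
        )

    def record(self, stage: str, key: str, outputs: list[Path], extra: dict | None = None) -> None:
        self.stages[stage] = {
            "key": key,
            "outputs": [str(o) for o in outputs],
            "checksums": {str(o): _sha256(Path(o)) for o in outputs},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **(extra or {}),
        }
        self.flush()

    def flush(self) -> None:
        self.path.write_text(json.dumps({"stages": self.stages}, indent=1))


def _stage_key(**params) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


def _log(out_dir: Path, event: str, **fields) -> None:
    with open(out_dir / "run.log", "a") as fh:
        fh.write(json.dumps({"event": event, "t": time.time(), **fields}) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dictionary.

    Stage outputs are left intact on partial failure, with the failing
    stage recorded in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    current_stage = "setup"
    try:
        # -- ingest / simulate -------------------------------------------
        current_stage = "cohort"
        cohort_path = out / "cohort.csv"
        outcomes_path = out / "outcomes.csv"
        if config.synthetic is not None:
            key = _stage_key(stage="simulate", spec=config.synthetic.__dict__, seed=config.synthetic.seed)
            if not manifest.up_to_date("cohort", key, [cohort_path, outcomes_path]):
                table, true_labels = generate_cohort(config.synthetic)
                table.to_csv(cohort_path)
                recs = generate_outcomes(true_labels, config.synthetic)
                outcomes_to_frame(recs).to_csv(outcomes_path, index=False)
                pd.DataFrame(
                    {"patient_id": table.patient_ids, "true_label": true_labels}
                ).to_csv(out / "true_labels.csv", index=False)
                manifest.record("cohort", key, [cohort_path, outcomes_path])
                _log(out, "simulated", n=table.n_patients, p=table.n_features)
        else:
            key = _stage_key(stage="ingest", checksum=_sha256(config.cohort_csv))
            if not manifest.up_to_date("cohort", key, [cohort_path]):
                CohortTable.read_csv(config.cohort_csv).to_csv(cohort_path)
                if config.outcomes_csv:
                    pd.read_csv(config.outcomes_csv).to_csv(outcomes_path, index=False)
                manifest.record("cohort", key, [cohort_path])
                _log(out, "ingested", source=str(config.cohort_csv))

        table = CohortTable.read_csv(cohort_path)

        # -- preprocess ---------------------------------------------------
        current_stage = "preprocess"
        prep_path = out / "standardized.csv"
        params_path = out / "scaling_params.json"
        key = _stage_key(stage="preprocess", cohort=_sha256(cohort_path))
        if not manifest.up_to_date("preprocess", key, [prep_path, params_path]):
            imputed = impute_median(table)
            std, params = standardize(imputed)
            std.to_csv(prep_path)
            params.to_json(params_path)
            manifest.record("preprocess", key, [prep_path, params_path])
            _log(out, "preprocessed")
        std = CohortTable.read_csv(prep_path)

        # -- clustering + significance ------------------------------------
        current_stage = "significance"
        labels_path = out / "labels.csv"
        heights_path = out / "heights.json"
        qq_path = out / "qq_pairs.csv"
        key = _stage_key(
            stage="significance",
            table=_sha256(prep_path),
            alphas=config.alpha_ladder,
            reps=config.n_reps,
            seed=config.seed,
            normalize=config.normalize_distance,
        )
        if not manifest.up_to_date("significance", key, [labels_path, heights_path, qq_path]):
            dend = agglomerate_complete(
                pairwise_distance(std, normalize=config.normalize_distance)
            )
            ref = reference_distribution(
                std, n_reps=config.n_reps, seed=config.seed, normalize=config.normalize_distance
            )
            cuts = significance_ladder(dend, ref, config.alpha_ladder)
            frame = pd.DataFrame({"patient_id": std.patient_ids})
            for cut in cuts:
                frame[f"cluster_alpha_{cut.alpha:g}"] = cut.labels.labels
            frame.to_csv(labels_path, index=False)
            with open(heights_path, "w") as fh:
                json.dump(
                    {
                        "D_0": np.sort(dend.heights).tolist(),
                        "D_ref": ref.values.tolist(),
                        "thresholds": {f"{c.alpha:g}": c.threshold_height for c in cuts},
                        "n_clusters": {f"{c.alpha:g}": c.n_clusters for c in cuts},
                    },
                    fh,
                    indent=1,
                )
            pd.DataFrame(qq_pairs(dend, ref), columns=["expected", "observed"]).to_csv(
                qq_path, index=False
            )
            manifest.record("significance", key, [labels_path, heights_path, qq_path])
            _log(out, "significance", n_clusters={f"{c.alpha:g}": c.n_clusters for c in cuts})

        labels_frame = pd.read_csv(labels_path)
        primary = ClusterAssignment(
            labels_frame[f"cluster_alpha_{config.alpha:g}"].to_numpy()
        )

        # -- LOFO ---------------------------------------------------------
        if config.run_lofo:
            current_stage = "lofo"
            lofo_path = out / "lofo.csv"
            key = _stage_key(
                stage="lofo", table=_sha256(prep_path), alpha=config.alpha,
                reps=config.n_reps, seed=config.seed,
            )
            if not manifest.up_to_date("lofo", key, [lofo_path]):
                results = lofo_table(std, alpha=config.alpha, reps=config.n_reps, seed=config.seed)
                pd.DataFrame(
                    [
                        {
                            "feature": r.feature_name,
                            "n_clusters_without": r.n_clusters_without,
                            "concordance_abs": r.concordance_abs,
                            "degenerate": r.degenerate,
                        }
                        for r in results
                    ]
                ).to_csv(lofo_path, index=False)
                manifest.record("lofo", key, [lofo_path])
                _log(out, "lofo", n_features=std.n_features)

        # -- naive Bayes ---------------------------------------------------
        current_stage = "classifier"
        model_path = out / "nb_model.json"
        key = _stage_key(stage="classifier", table=_sha256(prep_path), labels=_sha256(labels_path))
        if primary.n_clusters >= 2 and not manifest.up_to_date("classifier", key, [model_path]):
            model = nb_fit(std, primary)
            model.to_json(model_path)
            acc = lofo_cv_accuracy(std, primary)
            extra = {"lofo_cv_accuracy": acc}
            if config.validation_csv:
                vtab = CohortTable.read_csv(config.validation_csv, cohort_tag="validation")
                pred, post = predict_table(model, vtab)
                vout = pd.DataFrame({"patient_id": vtab.patient_ids, "cluster": pred})
                for i, c in enumerate(model.classes):
                    vout[f"posterior_{c}"] = post[:, i]
                vout.to_csv(out / "validation_labels.csv", index=False)
            manifest.record("classifier", key, [model_path], extra)
            _log(out, "classifier", **extra)

        # -- outcomes ------------------------------------------------------
        current_stage = "outcomes"
        if outcomes_path.exists():
            adj_path = out / "cci_adjudication.csv"
            key = _stage_key(stage="outcomes", outcomes=_sha256(outcomes_path))
            if not manifest.up_to_date("outcomes", key, [adj_path]):
                recs = outcomes_from_frame(pd.read_csv(outcomes_path))
                pd.DataFrame(
                    [{"patient_id": r.patient_id, "category": classify_cci(r)} for r in recs]
                ).to_csv(adj_path, index=False)
                manifest.record("outcomes", key, [adj_path])
                _log(out, "outcomes", n=len(recs))

        # -- SOM mosaics ---------------------------------------------------
        current_stage = "mosaic"
        key = _stage_key(
            stage="mosaic", table=_sha256(prep_path), labels=_sha256(labels_path),
            rows=config.som_rows, cols=config.som_cols, epochs=config.som_epochs,
            seed=config.seed,
        )
        mosaic_paths = [out / "mosaic_cohort.csv", out / "mosaic_color_scale.json"]
        if not manifest.up_to_date("mosaic", key, mosaic_paths):
            grid = train_som(
                std, rows=config.som_rows, cols=config.som_cols,
                epochs=config.som_epochs, seed=config.seed,
            )
            np.savetxt(mosaic_paths[0], cluster_mosaic(grid, std, None), delimiter=",")
            for c in sorted(set(primary.labels)):
                np.savetxt(
                    out / f"mosaic_cluster_{c}.csv",
                    cluster_mosaic(grid, std, primary, c),
                    delimiter=",",
                )
            grid.color_scale_json(mosaic_paths[1])
            manifest.record("mosaic", key, mosaic_paths)
            _log(out, "mosaic", rows=grid.rows, cols=grid.cols)

    except Exception as exc:  # record the failing stage, keep prior outputs
        manifest.stages["failure"] = {"stage": current_stage, "error": repr(exc)}
        manifest.flush()
        _log(out, "failure", stage=current_stage, error=repr(exc))
        raise

    return {"stages": manifest.stages}
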