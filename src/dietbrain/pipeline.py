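"""End-to-end orchestration: generate -> score -> impute -> associate -> mediate.

Produces a cohort-description table (mean/SD, median/IQR or percentages),
tidy association tables for the volume and IQ families under models 1 and
2 with Benjamini-Hochberg flags, and per-mediator quasi-Bayesian mediation
summaries — every artifact stamped with the configuration hash and the
stage seeds derived from one global seed.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import associate, cohort, impute, mediate, scoring

__all__ = ["PipelineConfig", "run_pipeline", "describe_cohort", "stage_seeds"]

SKEW_THRESHOLD = 1.0  # |skewness| above which a column is reported as median/IQR

_MEDIATORS = ["tbv_10", "white_10", "gray_10", "subcortical_10"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full pipeline run."""

    generator: cohort.GeneratorConfig = field(default_factory=cohort.GeneratorConfig)
    imputation: str | dict = "complete-case"  # or {"m": 10, "iterations": 50}
    families: tuple = ("volumes", "iq")
    models: tuple = (1, 2)
    mediators: tuple = tuple(_MEDIATORS)
    n_sims: int = 1000
    fdr: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        gen = cohort.GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(generator=gen, **raw)
        for key in ("families", "models", "mediators"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def hash(self) -> str:
        import hashlib

        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds derived from one global seed (< 2^31)."""
    names = ["generate", "missingness", "impute", "mediate"]
    ss = np.random.SeedSequence(global_seed)
    state = ss.generate_state(len(names)) % (2 ** 31)
    return {name: int(s) for name, s in zip(names, state)}


def describe_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort description: mean (SD), median (IQR) for skewed columns, or %.

    Continuous columns with |sample skewness| > 1 are summarised as
    median/IQR, others as mean/SD; categorical columns as category
    percentages (which sum to 100 within a variable).
    """
    rows = []
    for col in table.columns:
        if col == "id":
            continue
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            counts = s.value_counts(dropna=True)
            total = counts.sum()
            for level, cnt in counts.items():
                rows.append({"variable": col, "statistic": f"% {level}",
                             "value": 100.0 * cnt / total})
        else:
            x = s.dropna().to_numpy(dtype=float)
            if len(x) > 2 and x.std() > 0 and abs(stats.skew(x)) > SKEW_THRESHOLD:
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                rows.append({"variable": col, "statistic": "median", "value": med})
                rows.append({"variable": col, "statistic": "IQR_low", "value": q1})
                rows.append({"variable": col, "statistic": "IQR_high", "value": q3})
            else:
                rows.append({"variable": col, "statistic": "mean", "value": x.mean()})
                rows.append({"variable": col, "statistic": "SD",
                             "value": x.std(ddof=1) if len(x) > 1 else 0.0})
    return pd.DataFrame(rows)


def _association_table(data, families, models, fdr) -> pd.DataFrame:
    rows = []
    for family in families:
        for model in models:
            for res in associate.run_family(data, family=family, model=model, fdr=fdr):
                rows.append({"family": family, **res.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages, writing CSV/JSON artifacts plus a MANIFEST.

    Stage failures abort with the failing stage named; partial outputs are
    retained and the manifest marks the run incomplete.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"config_hash": config.hash(), "config": asdict(config),
                "stage_seeds": seeds, "complete": False, "stages": [], "files": []}

    def _write_manifest():
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str))

    def _stage(name):
        manifest["stages"].append(name)
        _write_manifest()

    stage = "generate"
    try:
        gen_cfg = cohort.GeneratorConfig(**{**asdict(config.generator), "seed": seeds["generate"]})
        table = cohort.generate_cohort(gen_cfg)
        cohort.write_cohort(table, outdir / "cohort.csv", gen_cfg)
        manifest["files"] += ["cohort.csv", "cohort.truth.json"]
        manifest["n_dyads"] = len(table)
        _stage(stage)

        stage = "score"
        scores = scoring.score_table(table[cohort.INTAKE_COLUMNS])
        scores.insert(0, "id", table["id"].to_numpy())
        scores.to_csv(outdir / "scores.csv", index=False)
        manifest["files"].append("scores.csv")
        _stage(stage)

        stage = "describe"
        describe_cohort(table).to_csv(outdir / "table1_cohort_description.csv", index=False)
        manifest["files"].append("table1_cohort_description.csv")
        _stage(stage)

        stage = "missingness+imputation"
        if config.imputation == "complete-case":
            data = table
        else:
            with_missing = cohort.inject_missingness(
                table, config.generator.missingness_rates, seed=seeds["missingness"])
            imp = impute.impute_chained(
                with_missing, m=int(config.imputation["m"]),
                iterations=int(config.imputation["iterations"]), seed=seeds["impute"])
            data = imp
        _stage(stage)

        stage = "associate"
        assoc = _association_table(data, config.families, config.models, config.fdr)
        vol = assoc[assoc["family"] == "volumes"]
        iqf = assoc[assoc["family"] == "iq"]
        if len(vol):
            vol.to_csv(outdir / "table2_volumes.csv", index=False)
            manifest["files"].append("table2_volumes.csv")
        if len(iqf):
            iqf.to_csv(outdir / "table3_iq.csv", index=False)
            manifest["files"].append("table3_iq.csv")
        _stage(stage)

        stage = "mediate"
        med_results = []
        for i, mediator in enumerate(config.mediators):
            spec = mediate.MediationSpec(mediator=mediator, n_sims=config.n_sims,
                                         seed=(seeds["mediate"] + i) % (2 ** 31))
            if isinstance(data, impute.ImputationSet):
                res = mediate.mediate_pooled(spec, data)
            else:
                res = mediate.mediate_quasi_bayes(spec, data)
            med_results.append(res.to_dict())
        (outdir / "mediation.json").write_text(json.dumps(med_results, indent=2))
        manifest["files"].append("mediation.json")
        _stage(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["complete"] = True
    _write_manifest()
    return manifest
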