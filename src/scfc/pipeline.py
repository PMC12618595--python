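"""Config-driven orchestration: simulate -> predict -> evaluate.

A run is reproducible from its YAML config plus one master seed; the master
seed fans out to per-stage seeds by fixed offsets.  Completed stages are
cached: a stage re-runs only when the checksum of its inputs changes.  Each
run writes a manifest recording the config, package version, stage
checksums and realized seeds.
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

from . import __version__
from .analytical import predict_cohort
from .core import Cohort, ConnectomeError, read_cohort
from .synthetic import GroundTruthMapping, SynthConfig, generate_cohort, write_synthetic_cohort
from . import stats as st

STAGE_SEED_OFFSETS = {"simulate": 0, "analytical": 1, "gmha": 2, "evaluate": 3}

DEFAULT_ANALYSES = (
    "accuracy",
    "ttests",
    "shuffle",
    "age",
    "groups",
    "panss",
    "strength",
    "variability",
)


class PipelineError(ConnectomeError):
    """A pipeline stage failed."""


@dataclass
class RunConfig:
    """Serializable description of one end-to-end run."""

    seed: int
    out_dir: str
    cohort_dir: str | None = None  # pre-existing cohort; else synthesize
    synthetic: dict = field(default_factory=dict)
    weights: list = field(default_factory=lambda: ["FA"])
    bands: list = field(default_factory=lambda: ["delta", "theta", "alpha", "beta"])
    models: list = field(default_factory=lambda: ["analytical"])
    analyses: list = field(default_factory=lambda: list(DEFAULT_ANALYSES))
    n_shuffle: int = 100
    alpha: float = 0.05
    gmha: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw or "out_dir" not in raw:
            raise PipelineError("config must be a mapping with seed and out_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _checksum_paths(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(map(Path, paths)):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed * 7919 + STAGE_SEED_OFFSETS[stage]) % (2**31)


def build_cohort(config: RunConfig) -> tuple[Cohort, Path]:
    """Load or synthesize the cohort; returns (cohort, directory)."""
    out = Path(config.out_dir)
    if config.cohort_dir:
        cdir = Path(config.cohort_dir)
        if not cdir.exists():
            raise PipelineError(f"cohort directory {cdir} does not exist")
        return read_cohort(cdir), cdir
    cdir = out / "cohort"
    stamp = cdir / ".synth_config.json"
    synth_kwargs = dict(config.synthetic)
    mapping_kwargs = synth_kwargs.pop("mapping", {})
    desc = json.dumps(
        {"synthetic": config.synthetic, "seed": _stage_seed(config, "simulate")},
        sort_keys=True,
    )
    if stamp.exists() and stamp.read_text() == desc:
        return read_cohort(cdir), cdir
    mapping = GroundTruthMapping(**mapping_kwargs)
    synth = SynthConfig(
        seed=_stage_seed(config, "simulate"), mapping=mapping, **synth_kwargs
    )
    cohort = generate_cohort(synth)
    write_synthetic_cohort(cohort, cdir)
    stamp.write_text(desc)
    return cohort, cdir


def run_analytical(config: RunConfig, cohort: Cohort) -> pd.DataFrame:
    out = Path(config.out_dir)
    records_path = out / "records_analytical.csv"
    cohort_sum = _checksum_paths((Path(config.cohort_dir or out / "cohort")).glob("*.csv"))
    stamp = out / ".analytical_inputs.json"
    desc = json.dumps(
        {"cohort": cohort_sum, "weights": config.weights, "bands": config.bands},
        sort_keys=True,
    )
    if records_path.exists() and stamp.exists() and stamp.read_text() == desc:
        return pd.read_csv(records_path, dtype={"subject": str})
    records = predict_cohort(cohort, weights=config.weights, bands=config.bands)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(records_path, index=False)
    stamp.write_text(desc)
    return records


def run_gmha(config: RunConfig, cohort: Cohort) -> pd.DataFrame:
    from .gmha import predict_external, save_crossval, train_crossval

    out = Path(config.out_dir)
    records_path = out / "records_gmha.csv"
    if records_path.exists():
        return pd.read_csv(records_path, dtype={"subject": str})
    seed = _stage_seed(config, "gmha")
    gmha_kwargs = dict(config.gmha)
    frames = []
    healthy = cohort.healthy
    patients = [s.id for s in cohort.patients]
    for weight in config.weights:
        for band in config.bands:
            result = train_crossval(
                cohort, band, weight, seed=seed, subjects=healthy, **gmha_kwargs
            )
            save_crossval(result, out / "gmha" / f"{band}_{weight}")
            frames.append(result.records)
            if patients:
                _, ext = predict_external(result, cohort, patients)
                frames.append(ext)
    records = pd.concat(frames, ignore_index=True)
    records.to_csv(records_path, index=False)
    return records


def run_evaluate(config: RunConfig, cohort: Cohort,
                 records: dict[str, pd.DataFrame]) -> dict:
    """All requested analyses; one CSV per analysis plus summary.json."""
    out = Path(config.out_dir) / "report"
    out.mkdir(parents=True, exist_ok=True)
    alpha = config.alpha
    seed = _stage_seed(config, "evaluate")
    groups = {s.id: s.group for s in cohort.subjects}
    ages = {s.id: s.age for s in cohort.subjects}
    healthy_ids = [s.id for s in cohort.healthy]
    summary: dict = {"alpha": alpha, "analyses": {}}

    def _mark(name, payload):
        summary["analyses"][name] = payload

    for model, recs in records.items():
        healthy_recs = recs[recs.subject.isin(healthy_ids)]
        if "accuracy" in config.analyses:
            acc = (
                healthy_recs.groupby(["band", "weight"]).r
                .agg(["mean", "std", "count"]).reset_index()
            )
            acc.to_csv(out / f"accuracy_{model}.csv", index=False)
            _mark(f"accuracy_{model}", {"mean_r": float(healthy_recs.r.mean())})
        if "ttests" in config.analyses and healthy_recs.weight.nunique() >= 2:
            df, thr = st.all_weight_pairs_ttests(healthy_recs, alpha=alpha)
            df.to_csv(out / f"ttests_{model}.csv", index=False)
            _mark(f"ttests_{model}", {"threshold": thr})
        if "age" in config.analyses:
            df = st.age_correlation(healthy_recs, ages, alpha=alpha)
            df.to_csv(out / f"age_{model}.csv", index=False)
            _mark(f"age_{model}", {"n_significant": int(df.significant.sum())})
        if "groups" in config.analyses and cohort.patients:
            df = st.group_comparison_records(recs, groups, alpha=alpha)
            df.to_csv(out / f"groups_{model}.csv", index=False)
            _mark(f"groups_{model}", {"n_significant": int(df.significant.sum())})
        if "panss" in config.analyses and len(cohort.patients) >= 3:
            panss = {s.id: s.panss for s in cohort.patients}
            df = st.spearman_panss(recs[recs.subject.isin(panss)], panss)
            df.to_csv(out / f"panss_{model}.csv", index=False)
            _mark(f"panss_{model}", {"min_p": float(df.p.min())})

    if "shuffle" in config.analyses and "analytical" in records:
        frames = []
        for weight in config.weights:
            for band in config.bands:
                scorer = st.analytical_shuffle_scorer(cohort, weight, band)
                df = st.shuffle_individuality(
                    healthy_ids, scorer, n_perm=config.n_shuffle, seed=seed
                )
                df["band"], df["weight"] = band, weight
                frames.append(df)
        shuffle_df = pd.concat(frames, ignore_index=True)
        shuffle_df.to_csv(out / "shuffle_analytical.csv", index=False)
        gap = (shuffle_df.r_unshuffled - shuffle_df.r_shuffled_mean).mean()
        _mark("shuffle_analytical", {"mean_gap": float(gap)})

    if "modelcompare" in config.analyses and len(records) == 2 and cohort.patients:
        pat = [s.id for s in cohort.patients]
        ra = records["gmha"]
        rb = records["analytical"]
        df = st.model_comparison(
            ra[ra.subject.isin(pat)], rb[rb.subject.isin(pat)], alpha=alpha
        )
        df.to_csv(out / "modelcompare.csv", index=False)
        _mark("modelcompare", {"n_significant": int(df.significant.sum())})

    if "strength" in config.analyses and cohort.patients:
        df = st.strength_group_comparison(cohort, alpha=alpha)
        df.to_csv(out / "strength.csv", index=False)
        _mark("strength", {"n_significant": int(df.significant.sum())})

    if "variability" in config.analyses:
        medians, tests = st.band_variability_comparison(cohort)
        medians.to_csv(out / "variability_medians.csv", index=False)
        tests.to_csv(out / "variability_tests.csv", index=False)
        _mark(
            "variability",
            {r.band: r.median_sd for r in medians.itertuples()},
        )

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> predict -> evaluate; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "seeds": {s: _stage_seed(config, s) for s in STAGE_SEED_OFFSETS},
    }

    def _stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        return result

    cohort, cdir = _stage("simulate", lambda: build_cohort(config))
    manifest["stages"]["simulate"]["checksum"] = _checksum_paths(cdir.glob("*.csv"))

    records = {}
    if "analytical" in config.models:
        records["analytical"] = _stage(
            "analytical", lambda: run_analytical(config, cohort)
        )
    if "gmha" in config.models:
        records["gmha"] = _stage("gmha", lambda: run_gmha(config, cohort))
    for model, recs in records.items():
        manifest["stages"][model]["n_records"] = len(recs)

    summary = _stage("evaluate", lambda: run_evaluate(config, cohort, records))
    manifest["summary"] = summary
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report_summary(report_dir) -> str:
    """Markdown table of r distributions and test outcomes from a report dir."""
    report_dir = Path(report_dir)
    summary_path = report_dir / "summary.json"
    if not summary_path.exists():
        raise PipelineError(f"{report_dir} has no summary.json (evaluate stage missing)")
    lines = ["| analysis | key | value |", "|---|---|---|"]
    summary = json.loads(summary_path.read_text())
    for name, payload in summary.get("analyses", {}).items():
        for key, value in payload.items():
            if isinstance(value, float):
                value = f"{value:.6g}"
            lines.append(f"| {name} | {key} | {value} |")
    for acc_file in sorted(report_dir.glob("accuracy_*.csv")):
        df = pd.read_csv(acc_file)
        model = acc_file.stem.split("_", 1)[1]
        for row in df.itertuples():
            lines.append(
                f"| r_distribution | {model}/{row.band}/{row.weight} | "
                f"{row.mean:.6g} +/- {0.0 if np.isnan(row.std) else row.std:.6g} "
                f"(n={row.count}) |"
            )
    return "\n".join(lines)
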