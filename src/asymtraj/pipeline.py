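"""End-to-end orchestration: simulate -> align -> validate -> fit.

A single YAML config drives the four pipeline stages (data creation, time
adjustment, reference-time evaluation, spline regression).  Every stage
writes plain CSV intermediates plus a JSON manifest recording parameters,
seeds and input hashes, so any stage can be inspected or recomputed, and a
rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import align, io, segfit, synth
from .features import RegistrationOptions, compute_all_features

__all__ = ["ConfigError", "load_config", "run_pipeline", "demo_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Config file fails validation before any stage runs."""


_DEFAULTS = {
    "cohort": {
        "n_subjects": 150,
        "visit_grid_months": list(synth.DEFAULT_VISIT_GRID),
        "converter_fraction": 0.28,
        "static_mix": [0.25, 0.45, 0.30],
        "covariate_noise_sd": 0.0,
    },
    "volumes": {"n": 0, "shape": [64, 64, 64], "n_pairs": 2},
    "match": {"k": 5, "n_replicates": 1000, "ranges": None},
    "validate": {"n_boot": 1000, "alpha": 0.05, "max_replicates": None},
    "fit": {
        "variables": "all",
        "alpha": 0.05,
        "min_per_segment": 10,
        "min_points": 20,
        "min_curve_n": 5,
    },
}


def load_config(path) -> dict:
    """Load and validate a pipeline config; missing sections get defaults.

    A missing top-level ``seed`` is a validation error: every stochastic
    stage must be reproducible.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    if "seed" not in raw:
        raise ConfigError("config must set a top-level integer 'seed'")
    if not isinstance(raw["seed"], int):
        raise ConfigError(f"seed must be an integer, got {raw['seed']!r}")
    cfg = {"seed": raw["seed"]}
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        user = raw.get(section, {}) or {}
        unknown = set(user) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
        merged.update(user)
        cfg[section] = merged
    frac = cfg["cohort"]["converter_fraction"]
    if not 0.0 <= frac <= 1.0:
        raise ConfigError(f"converter_fraction must be in [0,1], got {frac}")
    return cfg


def demo_config() -> dict:
    """The packaged small-scale demo configuration."""
    from importlib import resources

    with resources.files("asymtraj.data").joinpath("demo_config.yaml").open() as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict, out_dir, resume: bool = False) -> dict:
    """Run the four pipeline stages and return the manifest.

    Stage order: (1) synthesize the cohort (and optional paired volumes with
    their asymmetry features), apply the inclusion filter; (2) anchor all
    timelines to the conversion event, imputing static subjects, and build
    the top-k replicates; (3) validate the imputation by bootstrapped KS
    tests; (4) fit the segmented models and order the biomarkers.

    With ``resume=True``, stages whose outputs already exist under an
    identical config hash are skipped.  Partial outputs of a failing stage
    are preserved and the failure is logged with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    manifest_path = out / "manifest.json"
    old_manifest = None
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            old_manifest = old

    manifest: dict = {
        "config": config,
        "config_hash": cfg_hash,
        "seed": config["seed"],
        "stages": [],
    }

    def _done_before(name: str, outputs: list[str]) -> bool:
        if old_manifest is None:
            return False
        prior = {s["name"]: s for s in old_manifest["stages"]}
        done = name in prior and all((out / f).exists() for f in outputs)
        if done:
            # carry the prior record forward so the manifest stays complete
            manifest["stages"].append(prior[name])
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            logger.info("stage %s skipped (resume)", name)
        return done

    def _record(name: str, outputs: list[str], info: dict | None = None) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "completed": True,
                "outputs": outputs,
                "output_hashes": {f: _sha256(out / f) for f in outputs},
                "info": info or {},
            }
        )
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    seed = config["seed"]
    try:
        # ---- stage 1: data creation -------------------------------------
        stage = "synthesize"
        outputs = ["cohort.csv", "truth_subjects.csv", "truth_biomarkers.csv",
                   "exclusions.csv"]
        vol_cfg = config["volumes"]
        if vol_cfg["n"] > 0:
            outputs.append("features.csv")
        if not _done_before(stage, outputs):
            cc = config["cohort"]
            sim = synth.simulate_cohort(
                n_subjects=cc["n_subjects"],
                visit_grid_months=cc["visit_grid_months"],
                converter_fraction=cc["converter_fraction"],
                static_mix=tuple(cc["static_mix"]),
                covariate_noise_sd=cc["covariate_noise_sd"],
                seed=seed,
            )
            filtered, exclusions = io.filter_cohort(sim.visits)
            filtered.to_csv(out / "cohort.csv", index=False)
            sim.subjects.to_csv(out / "truth_subjects.csv", index=False)
            sim.biomarkers.to_csv(out / "truth_biomarkers.csv", index=False)
            exclusions.to_csv(out / "exclusions.csv", index=False)
            if vol_cfg["n"] > 0:
                feats = []
                pair_table = io.default_pair_table().head(vol_cfg["n_pairs"])
                for i in range(vol_cfg["n"]):
                    spec = synth.ShapeSpec(
                        shape_perturbation=0.05 * (i + 1),
                        seed=seed + 1000 + i,
                    )
                    pv = synth.make_paired_volume(
                        spec, shape=tuple(vol_cfg["shape"])
                    )
                    f = compute_all_features(
                        pv.volume, pair_table.head(1), RegistrationOptions()
                    )
                    f.insert(0, "volume_id", i)
                    feats.append(f)
                pd.concat(feats, ignore_index=True).to_csv(
                    out / "features.csv", index=False
                )
            _record(stage, outputs)
        logger.info("stage %s complete", stage)

        # ---- stage 2: time adjustment -----------------------------------
        stage = "align"
        outputs = ["adjusted.csv", "replicates.csv", "align_meta.json"]
        if not _done_before(stage, outputs):
            cohort = pd.read_csv(out / "cohort.csv")
            mc = align.MatchConfig(
                k=config["match"]["k"],
                n_replicates=config["match"]["n_replicates"],
                ranges=config["match"]["ranges"],
                seed=seed,
            )
            replicates, meta = align.build_replicates(cohort, mc)
            original = replicates[replicates["replicate_id"] == 0]
            original.to_csv(out / "adjusted.csv", index=False)
            replicates.to_csv(out / "replicates.csv", index=False)
            (out / "align_meta.json").write_text(
                json.dumps(meta, indent=2, default=str)
            )
            _record(stage, outputs, {"ranges": meta["ranges"]})
        logger.info("stage %s complete", stage)

        # ---- stage 3: evaluation of reference time ----------------------
        stage = "validate"
        outputs = ["ks.csv"]
        if not _done_before(stage, outputs):
            replicates = pd.read_csv(out / "replicates.csv")
            original = replicates[replicates["replicate_id"] == 0]
            vc = config["validate"]
            reps = replicates
            if vc["max_replicates"]:
                reps = replicates[replicates["replicate_id"] <= vc["max_replicates"]]
            ks = align.ks_validate(
                original["adjusted_months"].to_numpy(float),
                reps,
                n_boot=vc["n_boot"],
                alpha=vc["alpha"],
                seed=seed,
            )
            ks.to_csv(out / "ks.csv", index=False)
            _record(stage, outputs, align.ks_summary(ks) if len(ks) else {})
        logger.info("stage %s complete", stage)

        # ---- stage 4: spline regression ---------------------------------
        stage = "fit"
        outputs = ["fits.csv", "ordering.csv", "ordering_excluded.csv"]
        if not _done_before(stage, outputs):
            cohort = pd.read_csv(out / "cohort.csv")
            adjusted = pd.read_csv(out / "adjusted.csv")
            merged = cohort.merge(
                adjusted[["rid", "viscode_months", "adjusted_months"]],
                on=["rid", "viscode_months"],
            )
            fc = config["fit"]
            variables = fc["variables"]
            if variables == "all":
                skip = {"rid", "viscode_months", "diagnosis", "adjusted_months", "age"}
                variables = [c for c in merged.columns if c not in skip]
            opts = segfit.FitOptions(
                min_points=fc["min_points"],
                min_per_segment=fc["min_per_segment"],
                alpha=fc["alpha"],
            )
            fits = [
                segfit.fit_biomarker(
                    merged["adjusted_months"], merged[v], variable=v, opts=opts
                )
                for v in variables
            ]
            pd.DataFrame([vars(f) for f in fits]).to_csv(out / "fits.csv", index=False)
            ordered, excluded = segfit.order_biomarkers(fits)
            ordered.to_csv(out / "ordering.csv", index=False)
            excluded.to_csv(out / "ordering_excluded.csv", index=False)
            _record(stage, outputs)
        logger.info("stage %s complete", stage)
    except Exception:
        logger.exception("pipeline failed in stage %s; partial outputs kept", stage)
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise

    return manifest
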