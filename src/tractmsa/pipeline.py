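"""End-to-end orchestration: masks and scores in, contribution tables out.

Stages: load inputs -> disconnection profiles -> lesion-covariance
diagnostics -> behavioral labels -> per-test graded datasets ->
predictor validation -> bootstrap Shapley contributions ->
cross-test contributor classification.  Per-test subcohorts are formed
inside the pipeline from score missingness, never by pre-filtering
files.  Every run writes a machine-readable manifest (config, seed,
version, per-stage wall time) so outputs regenerate identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .behavior import TESTS, performance_labels, score_cohort
from .cohort_io import read_patient_table, summarize_cohort
from .disconnection import (
    ROB,
    TractAtlas,
    lesion_correlation_matrix,
    profiles_to_frame,
    profile_patient,
)
from .predictor import DEFAULT_KERNELS, GradedDataset, PredictorSpec, validate
from .shapley import bootstrap_contributions, classify_contributors, flag_significance
from .synthetic_cohort import DEFAULT_COMPLETE_COUNTS, generate_cohort, write_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixture"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("profiles", "behavior", "validate", "msa", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Everything a run needs; defaults reproduce the reference settings
    (1,000 permutations, 1,000 bootstrap resamples, c = 1, per-test
    kernels linear/polynomial/quadratic, atlas threshold 0.5)."""

    atlas_dir: str
    lesion_dir: str
    patient_table: str
    output_dir: str
    players: list[str] | None = None
    atlas_threshold: float = 0.5
    kernels: dict = field(default_factory=lambda: dict(DEFAULT_KERNELS))
    box_constraint: float = 1.0
    n_perms: int = 1000
    n_boot: int = 1000
    chance_reps: int = 1000
    seed: int = 0
    level: float = 0.05
    normalization: str = "sum_abs"
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        for key in ("atlas_dir", "lesion_dir", "patient_table", "output_dir"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate_paths(self) -> None:
        for key in ("atlas_dir", "lesion_dir", "patient_table"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise PipelineError(f"config: {key} does not exist: {p}")
        if not 0 < self.atlas_threshold < 1:
            raise PipelineError("config: atlas_threshold outside (0, 1)")
        for name in ("n_perms", "n_boot", "chance_reps"):
            if getattr(self, name) < 1:
                raise PipelineError(f"config: {name} must be >= 1")
        if not 0 < self.level < 1:
            raise PipelineError("config: level outside (0, 1)")


def _find_lesion(lesion_dir: Path, patient_id: str) -> Path:
    for pattern in (f"patient_{patient_id}.nii", f"patient_{patient_id}.nii.gz",
                    f"{patient_id}.nii", f"{patient_id}.nii.gz"):
        p = lesion_dir / pattern
        if p.exists():
            return p
    raise PipelineError(f"load: no lesion mask for patient {patient_id} in {lesion_dir}")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the chain and write outputs under ``config.output_dir``.

    Returns a dict of output paths plus the in-memory results.  Any
    stage failure aborts with the stage name; the manifest then records
    the run as incomplete.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "complete": False,
        "stages": {},
    }
    results: dict = {"output_dir": out}
    ss = np.random.SeedSequence(config.seed)
    test_seeds = {
        t: int(s.generate_state(1)[0] % (2**31)) for t, s in zip(TESTS, ss.spawn(len(TESTS)))
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except PipelineError:
                _write_manifest(out, manifest)
                raise
            except Exception as exc:
                _write_manifest(out, manifest)
                raise PipelineError(f"{name}: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            logger.info("stage %-10s %.2fs", name, dt)
        return deco

    @stage("load")
    def _load():
        atlas = TractAtlas.load(config.atlas_dir)
        if config.players:
            missing = set(config.players) - set(atlas.names)
            if missing:
                raise PipelineError(f"load: players not in atlas: {sorted(missing)}")
            atlas = TractAtlas(
                names=list(config.players),
                volumes={n: atlas.volumes[n] for n in config.players},
                pool=atlas.pool,
                affine=atlas.affine,
            )
        records = read_patient_table(config.patient_table)
        lesions = {}
        for rec in records:
            img = nib.load(_find_lesion(Path(config.lesion_dir), rec.id))
            mask = np.asarray(img.dataobj) > 0
            if mask.shape != atlas.grid_shape:
                raise PipelineError(
                    f"load: lesion for patient {rec.id} has grid {mask.shape}, "
                    f"atlas grid is {atlas.grid_shape}"
                )
            lesions[rec.id] = mask
        results.update(atlas=atlas, records=records, lesions=lesions)

    @stage("profiles")
    def _profiles():
        atlas = results["atlas"]
        profiles = [
            profile_patient(results["lesions"][rec.id], atlas,
                            config.atlas_threshold, patient_id=rec.id)
            for rec in results["records"]
        ]
        results["profiles"] = {p.patient_id: p for p in profiles}
        if "profiles" in stages:
            profiles_to_frame(profiles).to_csv(out / "profiles_fraction.csv")
            profiles_to_frame(profiles, percent=True).to_csv(out / "profiles_percent.csv")

    @stage("behavior")
    def _behavior():
        records = results["records"]
        if "behavior" in stages:
            score_cohort(records).to_csv(out / "behavior.csv", index=False)
            with open(out / "cohort_summary.json", "w") as fh:
                fh.write(summarize_cohort(records).to_json())
        datasets = {}
        for test in TESTS:
            ids, labels = performance_labels(records, test)
            if len(ids) == 0:
                continue
            X = np.vstack([results["profiles"][i].intact for i in ids])
            names = results["profiles"][ids[0]].player_names
            datasets[test] = GradedDataset(
                test=test, X=X, y=labels, patient_ids=tuple(ids), player_names=names
            )
            if "behavior" in stages:
                frame = profiles_to_frame([results["profiles"][i] for i in ids])
                frame = 1.0 - frame
                frame["performance"] = labels
                frame.to_csv(out / f"graded_{test}.csv")
        results["datasets"] = datasets

    @stage("correlations")
    def _correlations():
        if "profiles" not in stages:
            return
        for test, ds in results["datasets"].items():
            subprofiles = [results["profiles"][i] for i in ds.patient_ids]
            players = [n for n in subprofiles[0].player_names if n != ROB]
            corr = lesion_correlation_matrix(subprofiles, level=config.level, order=players)
            corr.r.to_csv(out / f"correlation_{test}.csv")
            corr.p.to_csv(out / f"correlation_{test}_pvalues.csv")
            if config.make_figures:
                from .plots import plot_correlation_heatmap

                plot_correlation_heatmap(corr, out / f"correlation_{test}.png")

    @stage("validate")
    def _validate():
        if "validate" not in stages and "report" not in stages:
            return
        reports = {}
        for test, ds in results["datasets"].items():
            spec = PredictorSpec(kernel=config.kernels.get(test, "linear"),
                                 box_constraint=config.box_constraint)
            reports[test] = validate(ds, spec, reps=config.chance_reps,
                                     seed=test_seeds[test])
        results["validation"] = reports
        with open(out / "validation.json", "w") as fh:
            json.dump({t: r.to_dict() for t, r in reports.items()}, fh, indent=2)

    @stage("msa")
    def _msa():
        if "msa" not in stages and "report" not in stages:
            return
        contributions = {}
        for test, ds in results["datasets"].items():
            spec = PredictorSpec(kernel=config.kernels.get(test, "linear"),
                                 box_constraint=config.box_constraint)
            res = bootstrap_contributions(
                ds, spec, n_boot=config.n_boot, n_perms=config.n_perms,
                seed=test_seeds[test], normalization=config.normalization,
            )
            contributions[test] = flag_significance(res, level=config.level)
        results["contributions"] = contributions
        import pandas as pd

        pd.concat([c.to_frame() for c in contributions.values()]).to_csv(
            out / "contributions.csv", index=False
        )
        if config.make_figures:
            from .plots import plot_contributions

            for test, c in contributions.items():
                plot_contributions(c, out / f"contributions_{test}.png")
        if len(contributions) >= 2:
            classification = classify_contributors(contributions)
            results["classification"] = classification
            classification.to_csv(out / "classification.csv")

    manifest["complete"] = True
    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def make_fixture(
    directory: str | Path,
    n_patients: int = 25,
    seed: int = 0,
    noise_sd: float = 0.1,
    reference_missingness: bool = True,
    n_perms: int = 1000,
    n_boot: int = 1000,
    **cohort_kwargs,
) -> Path:
    """Write a self-contained synthetic study directory plus config.

    The directory is accepted by :func:`run_pipeline` unchanged; the
    returned path is its ``config.yaml``.  Missingness defaults to the
    reference 23/24/19-of-25 completion pattern (scaled for other n).
    """
    directory = Path(directory)
    counts = None
    if reference_missingness:
        counts = {
            t: max(2, round(c * n_patients / 25))
            for t, c in DEFAULT_COMPLETE_COUNTS.items()
        }
    cohort = generate_cohort(
        n_patients=n_patients, seed=seed, noise_sd=noise_sd,
        complete_counts=counts, **cohort_kwargs,
    )
    write_cohort(cohort, directory)
    config = RunConfig(
        atlas_dir="atlas",
        lesion_dir="lesions",
        patient_table="patient_table.csv",
        output_dir="results",
        seed=seed,
        n_perms=n_perms,
        n_boot=n_boot,
    )
    config.to_yaml(directory / "config.yaml")
    return directory / "config.yaml"
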