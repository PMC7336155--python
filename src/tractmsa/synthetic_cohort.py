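"""Synthetic atlases, lesions, and behavior with a known ground truth.

No public imaging accession exists for chronic-neglect cohorts of the
kind this package analyses, so every downstream stage is exercised on
generated data whose lesion-behavior mapping is known by construction.
The generator emulates the statistical features the analysis relies on,
not anatomy:

* a probabilistic "atlas" of compact, mostly non-overlapping tract
  cores on a small 3-D grid, plus a pool of non-player tracts from
  which the rest-of-brain (RoB) region is formed;
* spatially contiguous lesion blobs grown from random seed voxels,
  with lognormally distributed extents, which induce graded per-tract
  damage fractions with low inter-tract correlation;
* binary task outcomes from a linear-threshold rule on tract
  intactness plus additive Gaussian noise — the minimal model under
  which the sign and rank of each player's true contribution are known
  recovery targets;
* per-test missingness injected completely at random, defaulting to
  the 23/24/19-of-25 completion pattern of the reference cohort.

Everything is a pure function of its arguments including the seed:
identical calls reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import nibabel as nib
import numpy as np

from .behavior import TESTS
from .cohort_io import PatientRecord, write_patient_table
from .disconnection import DisconnectionProfile, TractAtlas, profile_patient

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "DEFAULT_TRACT_NAMES",
    "DEFAULT_GRID",
    "DEFAULT_SIZE_DIST",
    "generate_atlas",
    "generate_lesions",
    "generate_behavior",
    "generate_cohort",
    "write_cohort",
]

#: the 11 bundle labels used for the visuospatial-attention player set
DEFAULT_TRACT_NAMES = (
    "SLF_I", "SLF_II", "SLF_III", "IFOF", "ILF", "CC",
    "ATP", "OR", "APS", "CA", "CP",
)

DEFAULT_GRID = (16, 16, 16)
#: lognormal lesion extent: (median voxels, sigma of log)
DEFAULT_SIZE_DIST = (300, 0.5)
#: default completion counts per test for a 25-patient cohort
DEFAULT_COMPLETE_COUNTS = {"line_bisection": 23, "bells": 24, "letter": 19}

#: benchmark ground-truth weights for recovery validation: 11 tracts
#: spanning strong-to-weak positive, three negative contributors, and a
#: small positive rest-of-brain weight (last entry)
RECOVERY_WEIGHTS = np.array(
    [1.0, 0.85, 0.7, 0.55, 0.45, 0.35, 0.25, -0.25, -0.45, -0.65, 0.15, 0.1]
)

SizeDist = int | tuple[float, float] | Callable[[np.random.Generator], int]


@dataclass(frozen=True)
class GroundTruth:
    """The linear-threshold rule generating one test's outcomes.

    latent = weights . intactness + N(0, noise_sd); the outcome is
    normal (performance 1) iff latent >= threshold.  Weights are signed
    and in arbitrary units; a negative weight makes damage of that
    player *improve* the latent performance (a paradoxical, negative
    contributor).
    """

    weights: np.ndarray
    noise_sd: float
    threshold: float
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticCohort:
    """A self-contained synthetic study: imaging, scores, and truth."""

    atlas: TractAtlas
    lesions: list[np.ndarray]
    records: list[PatientRecord]
    profiles: list[DisconnectionProfile]
    truths: dict[str, GroundTruth]
    performance: dict[str, np.ndarray]  # per test, over all patients
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.lesions)


def generate_atlas(
    grid_shape: Sequence[int] = DEFAULT_GRID,
    n_tracts: int = len(DEFAULT_TRACT_NAMES),
    seed: int = 0,
    radius: float | None = None,
    n_pool: int = 4,
    names: Sequence[str] | None = None,
) -> TractAtlas:
    """Generate a probabilistic atlas of compact tract cores.

    Each tract is an isotropic Gaussian probability profile around a
    centre, scaled so the supra-0.5 core is a ball of roughly the given
    radius (default scales with the grid: 15% of the smallest extent,
    at least 1.2 voxels).  Centres are placed by greedy best-candidate
    sampling to keep cores distinct (pairwise core overlap stays low);
    ``n_pool`` extra tracts are generated the same way and held outside
    the player set as the RoB pool.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 4 for g in grid_shape):
        raise ValueError(f"grid extents must all be >= 4, got {grid_shape}")
    if n_tracts < 2:
        raise ValueError("need at least 2 tracts")
    if radius is None:
        radius = max(1.2, 0.15 * min(grid_shape))
    if names is None:
        names = (
            list(DEFAULT_TRACT_NAMES)
            if n_tracts == len(DEFAULT_TRACT_NAMES)
            else [f"tract_{k + 1:02d}" for k in range(n_tracts)]
        )
    elif len(names) != n_tracts:
        raise ValueError("names length must equal n_tracts")

    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    lo = np.full(3, radius)
    hi = np.asarray(grid_shape, dtype=float) - 1 - radius
    hi = np.maximum(hi, lo)  # degenerate small grids still get a centre
    centers: list[np.ndarray] = []
    for _ in range(n_tracts + n_pool):
        best, best_sep = None, -1.0
        for _ in range(60):  # best-candidate: maximise nearest-centre distance
            cand = rng.uniform(lo, hi)
            sep = min((np.linalg.norm(cand - c) for c in centers), default=np.inf)
            if sep > best_sep:
                best, best_sep = cand, sep
        centers.append(best)
    sigma = radius / np.sqrt(2.0 * np.log(2.0))  # prob = 0.5 at r = radius
    vols = [
        np.exp(-((coords - c) ** 2).sum(axis=1) / (2 * sigma**2)).reshape(grid_shape)
        for c in centers
    ]
    volumes = {n: v for n, v in zip(names, vols[:n_tracts])}
    pool = {f"pool_{k + 1:02d}": v for k, v in enumerate(vols[n_tracts:])}
    return TractAtlas(names=list(names), volumes=volumes, pool=pool)


def _grow_blob(shape: tuple[int, ...], n_vox: int, rng: np.random.Generator) -> np.ndarray:
    """Region-grow a 6-connected blob of ``n_vox`` voxels."""
    mask = np.zeros(shape, dtype=bool)
    if n_vox <= 0:
        return mask
    n_vox = min(n_vox, int(np.prod(shape)))
    start = tuple(int(rng.integers(0, s)) for s in shape)
    mask[start] = True
    frontier = [start]
    count = 1
    steps = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while count < n_vox and frontier:
        idx = int(rng.integers(0, len(frontier)))
        x, y, z = frontier[idx]
        nbrs = [
            (x + dx, y + dy, z + dz)
            for dx, dy, dz in steps
            if 0 <= x + dx < shape[0]
            and 0 <= y + dy < shape[1]
            and 0 <= z + dz < shape[2]
            and not mask[x + dx, y + dy, z + dz]
        ]
        if not nbrs:
            frontier.pop(idx)
            continue
        p = nbrs[int(rng.integers(0, len(nbrs)))]
        mask[p] = True
        frontier.append(p)
        count += 1
    return mask


def _draw_size(size_dist: SizeDist, rng: np.random.Generator, volume: int) -> int:
    if callable(size_dist):
        n = int(size_dist(rng))
    elif isinstance(size_dist, tuple):
        median, sigma = size_dist
        # lognormal truncated at the grid volume (a whole-grid lesion)
        n = min(int(np.exp(rng.normal(np.log(median), sigma))), volume)
    else:
        n = int(size_dist)
    if n < 0 or n > volume:
        raise ValueError(f"lesion extent {n} outside [0, grid volume {volume}]")
    return n


def generate_lesions(
    atlas: TractAtlas,
    n_patients: int,
    size_dist: SizeDist = DEFAULT_SIZE_DIST,
    seed: int = 0,
) -> list[np.ndarray]:
    """One contiguous binary lesion blob per patient on the atlas grid.

    Extents are drawn from ``size_dist`` — an int (fixed), a
    ``(median, sigma)`` lognormal pair, or a callable on the RNG.  A
    zero-extent draw yields an empty mask (an unlesioned patient).
    """
    rng = np.random.default_rng(seed)
    shape = atlas.grid_shape
    volume = int(np.prod(shape))
    return [
        _grow_blob(shape, _draw_size(size_dist, rng, volume), rng)
        for _ in range(n_patients)
    ]


def generate_behavior(
    profiles: Sequence[DisconnectionProfile], truth: GroundTruth
) -> np.ndarray:
    """Binary performance labels (1 = normal) from the linear rule.

    latent_i = w . intact_i + eps_i with eps ~ N(0, noise_sd); the
    label is 1 iff latent_i >= truth.threshold.  With noise_sd = 0 this
    is exactly reproducible by evaluating the rule by hand.
    """
    X = np.vstack([p.intact for p in profiles])
    if X.shape[1] != len(truth.weights):
        raise ValueError(
            f"profiles have {X.shape[1]} players but truth has {len(truth.weights)} weights"
        )
    rng = np.random.default_rng(truth.seed)
    latent = X @ truth.weights
    if truth.noise_sd > 0:
        latent = latent + rng.normal(0.0, truth.noise_sd, size=len(latent))
    return (latent >= truth.threshold).astype(int)


def _raw_scores_for_label(
    test: str, performance: int, rng: np.random.Generator
) -> dict:
    """Draw raw scores consistent with a performance label.

    The draws re-binarize to the intended deficit under the clinical
    cut-offs, so a round trip through the scoring module reproduces the
    generated labels exactly.  Pathological draws follow the left-
    neglect phenotype (rightward bisection deviation, left-sided
    omissions).
    """
    if test == "line_bisection":
        if performance == 1:
            mm = rng.uniform(-7.0, 6.2)
        else:
            mm = rng.uniform(8.0, 70.0)
        return {"line_bisection_pct": round(mm / 2.0, 1)}  # pct of a 200 mm line
    if test == "bells":
        right = int(rng.integers(10, 16))
        if performance == 1:
            left = int(np.clip(right - rng.integers(-2, 3), 0, 15))
            if abs(right - left) > 2:  # clip pushed the diff out; recentre
                left = right
        else:
            left = max(0, right - int(rng.integers(3, 14)))
        return {"bells_left": left, "bells_right": right}
    if test == "letter":
        om_right = int(rng.integers(0, 4))
        if performance == 1:
            om_left = int(np.clip(om_right + rng.integers(-2, 3), 0, 30))
        else:
            om_left = min(30, om_right + int(rng.integers(3, 21)))
        return {"letter_left": 30 - om_left, "letter_right": 30 - om_right}
    raise ValueError(f"unknown test {test!r}")


def _inject_missingness(
    n: int,
    complete_counts: dict[str, int],
    rng: np.random.Generator,
    allow_all_missing: bool = False,
    max_tries: int = 1000,
) -> dict[str, np.ndarray]:
    """Choose, per test, which patients are missing (True = missing).

    Missingness is completely at random per test.  Unless explicitly
    allowed, the draw is constrained so no patient is missing from
    every test at once: each patient is first assigned one guaranteed
    test (probability proportional to its completion count), and each
    test's completion set is then filled up at random.
    """
    tests = list(complete_counts)
    if allow_all_missing or sum(complete_counts.values()) == 0:
        return {
            t: np.isin(np.arange(n), rng.choice(n, n - complete_counts[t], replace=False))
            for t in tests
        }
    if sum(complete_counts.values()) < n:
        raise ValueError(
            "completion counts sum below the patient count; "
            "every-test-missing patients are unavoidable"
        )
    probs = np.array([complete_counts[t] for t in tests], dtype=float)
    probs /= probs.sum()
    for _ in range(max_tries):
        guaranteed = rng.choice(len(tests), size=n, p=probs)
        if any(
            (guaranteed == k).sum() > complete_counts[t]
            for k, t in enumerate(tests)
        ):
            continue  # a test's guaranteed patients exceed its slots; redraw
        missing: dict[str, np.ndarray] = {}
        for k, t in enumerate(tests):
            present = set(np.flatnonzero(guaranteed == k))
            others = [i for i in range(n) if i not in present]
            extra = complete_counts[t] - len(present)
            present.update(rng.choice(others, size=extra, replace=False))
            missing[t] = ~np.isin(np.arange(n), sorted(present))
        return missing
    raise RuntimeError("could not draw a missingness pattern keeping every patient in some test")


def generate_cohort(
    n_patients: int = 25,
    grid_shape: Sequence[int] = DEFAULT_GRID,
    n_tracts: int = len(DEFAULT_TRACT_NAMES),
    seed: int = 0,
    noise_sd: float = 0.1,
    weights: dict[str, np.ndarray] | None = None,
    size_dist: SizeDist = DEFAULT_SIZE_DIST,
    complete_counts: dict[str, int] | None = None,
    patho_rate: float = 0.45,
    atlas_threshold: float = 0.5,
) -> SyntheticCohort:
    """Generate a full synthetic study with known ground truth.

    Per test, ground-truth weights default to magnitudes drawn uniform
    on [0.15, 1] with a 25% chance of a negative sign (negative
    contributors exist in real cohorts); the latent threshold is set at
    the ``patho_rate`` quantile of the noiseless latent performance so
    roughly that share of patients is pathological.  ``complete_counts``
    (per-test completed patients) defaults to all-complete; pass the
    reference 23/24/19 pattern to emulate the clinical table.
    """
    ss = np.random.SeedSequence(seed)
    s_atlas, s_lesion, s_truth, s_raw, s_miss = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    atlas = generate_atlas(grid_shape, n_tracts, seed=s_atlas)
    lesions = generate_lesions(atlas, n_patients, size_dist, seed=s_lesion)
    profiles = [
        profile_patient(les, atlas, atlas_threshold, patient_id=str(i + 1))
        for i, les in enumerate(lesions)
    ]
    n_players = len(profiles[0].player_names)

    rng_truth = np.random.default_rng(s_truth)
    truths: dict[str, GroundTruth] = {}
    performance: dict[str, np.ndarray] = {}
    X = np.vstack([p.intact for p in profiles])
    for k, test in enumerate(TESTS):
        if weights is not None and test in weights:
            w = np.asarray(weights[test], dtype=float)
            if len(w) != n_players:
                raise ValueError(f"{test}: expected {n_players} weights, got {len(w)}")
        else:
            mag = rng_truth.uniform(0.15, 1.0, size=n_players)
            sign = np.where(rng_truth.uniform(size=n_players) < 0.25, -1.0, 1.0)
            w = mag * sign
        thresh = float(np.quantile(X @ w, patho_rate))
        truth = GroundTruth(
            weights=w, noise_sd=noise_sd, threshold=thresh, seed=s_truth + 7 * k + 1
        )
        truths[test] = truth
        performance[test] = generate_behavior(profiles, truth)

    rng_raw = np.random.default_rng(s_raw)
    rng_miss = np.random.default_rng(s_miss)
    counts = dict(complete_counts or {t: n_patients for t in TESTS})
    for t in TESTS:
        counts.setdefault(t, n_patients)
        if not 0 <= counts[t] <= n_patients:
            raise ValueError(f"complete count for {t} outside [0, {n_patients}]")
    missing = _inject_missingness(n_patients, counts, rng_miss)

    records: list[PatientRecord] = []
    for i in range(n_patients):
        fields: dict = {
            "id": str(i + 1),
            "sex": "M" if rng_raw.uniform() < 0.68 else "F",
            "age": int(np.clip(round(rng_raw.normal(56.0, 10.6)), 18, 90)),
            "onset": int(np.clip(round(np.exp(rng_raw.normal(np.log(150.0), 0.8))), 60, 1500)),
            "etiology": "Ischemic" if rng_raw.uniform() < 0.6 else "Hemorrhagic",
            "visual_field": str(
                rng_raw.choice(["Normal", "Left extinction", "Left hemianopia"])
            ),
        }
        for test in TESTS:
            if missing[test][i]:
                continue
            fields.update(_raw_scores_for_label(test, int(performance[test][i]), rng_raw))
        records.append(PatientRecord(**fields))

    return SyntheticCohort(
        atlas=atlas,
        lesions=lesions,
        records=records,
        profiles=profiles,
        truths=truths,
        performance=performance,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write a cohort as a runnable study directory.

    Layout: ``atlas/*.nii`` (+ ``atlas/pool/``), ``lesions/patient_*.nii``,
    ``patient_table.csv`` and a ``ground_truth.json`` sidecar recording
    the generating weights per test.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.atlas.save(directory / "atlas")
    lesion_dir = directory / "lesions"
    lesion_dir.mkdir(exist_ok=True)
    for rec, mask in zip(cohort.records, cohort.lesions):
        img = nib.Nifti1Image(mask.astype(np.uint8), cohort.atlas.affine)
        nib.save(img, lesion_dir / f"patient_{rec.id}.nii")
    write_patient_table(cohort.records, directory / "patient_table.csv")
    truth = {
        "seed": cohort.seed,
        "player_names": list(cohort.profiles[0].player_names),
        "tests": {
            t: {
                "weights": cohort.truths[t].weights.tolist(),
                "noise_sd": cohort.truths[t].noise_sd,
                "threshold": cohort.truths[t].threshold,
                "seed": cohort.truths[t].seed,
            }
            for t in cohort.truths
        },
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2))
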