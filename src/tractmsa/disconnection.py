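"""Tract disconnection metrics from lesion masks and a probabilistic atlas.

The damage a lesion inflicts on a white-matter bundle is summarised by
the disconnection fraction

    d(lesion, bundle) = |lesion ∩ bundle| / |bundle|

computed on voxel counts after binarizing the bundle's probability map
(threshold 0.5 by default; the atlas gives per-voxel membership
probabilities).  The rest-of-brain (RoB) player aggregates the pool of
bundles *not* chosen as players: its fraction is the lesioned share of
the union of pool bundles, with voxels also belonging to a player
bundle excluded so nothing is double-counted.  Intactness, the input to
the coalition analysis, is ``1 - d`` per player.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TractAtlas",
    "DisconnectionProfile",
    "CorrelationResult",
    "ROB",
    "binarize_tract",
    "disconnection_fraction",
    "rob_fraction",
    "profile_patient",
    "profiles_to_frame",
    "lesion_correlation_matrix",
]

#: name of the compound rest-of-brain player, appended after the tracts
ROB = "RoB"


class GridMismatchError(ValueError):
    """Masks or volumes do not share the atlas voxel grid."""


@dataclass
class TractAtlas:
    """Named probabilistic tract volumes on a shared voxel grid.

    ``volumes`` maps each player tract to its probability map; ``pool``
    holds additional maps outside the player set, from which the RoB
    region is formed.  Voxel grids are index-based: masks must already
    be registered to the atlas grid (no resampling is attempted).
    """

    names: list[str]
    volumes: dict[str, np.ndarray]
    pool: dict[str, np.ndarray] = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("tract names must be unique")
        if set(self.names) != set(self.volumes):
            raise ValueError("names and volumes keys must match")
        shapes = {v.shape for v in self.volumes.values()} | {
            v.shape for v in self.pool.values()
        }
        if len(shapes) != 1:
            raise GridMismatchError(f"volumes on inconsistent grids: {shapes}")
        for name, vol in list(self.volumes.items()) + list(self.pool.items()):
            if vol.min() < 0 or vol.max() > 1:
                raise ValueError(f"tract {name!r}: probabilities outside [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    def binary_masks(self, threshold: float = 0.5) -> dict[str, np.ndarray]:
        return {n: binarize_tract(v, threshold) for n, v in self.volumes.items()}

    def pool_masks(self, threshold: float = 0.5) -> dict[str, np.ndarray]:
        return {n: binarize_tract(v, threshold) for n, v in self.pool.items()}

    def save(self, directory: str | Path) -> None:
        """Write each probability map as an uncompressed NIfTI volume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, vol in self.volumes.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine),
                     directory / f"{name}.nii")
        pool_dir = directory / "pool"
        pool_dir.mkdir(exist_ok=True)
        for name, vol in self.pool.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine),
                     pool_dir / f"{name}.nii")

    @classmethod
    def load(cls, directory: str | Path) -> "TractAtlas":
        directory = Path(directory)
        volumes: dict[str, np.ndarray] = {}
        affine = np.eye(4)
        for path in sorted(directory.glob("*.nii*")):
            img = nib.load(path)
            volumes[path.name.split(".nii")[0]] = np.asarray(img.dataobj, dtype=float)
            affine = img.affine
        pool: dict[str, np.ndarray] = {}
        pool_dir = directory / "pool"
        if pool_dir.is_dir():
            for path in sorted(pool_dir.glob("*.nii*")):
                pool[path.name.split(".nii")[0]] = np.asarray(
                    nib.load(path).dataobj, dtype=float
                )
        if not volumes:
            raise FileNotFoundError(f"no NIfTI tract volumes under {directory}")
        return cls(names=sorted(volumes), volumes=volumes, pool=pool, affine=affine)


@dataclass(frozen=True)
class DisconnectionProfile:
    """Per-patient damaged fractions over the players (tracts + RoB)."""

    patient_id: str
    player_names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.player_names),):
            raise ValueError("d length must equal number of players")
        if d.min() < 0 or d.max() > 1:
            raise ValueError("damaged fractions must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    @property
    def intact(self) -> np.ndarray:
        return 1.0 - self.d


def binarize_tract(prob_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a boolean tract mask.

    A voxel belongs to the tract iff its probability is >= threshold.
    An empty result is permitted but warned about, since a downstream
    disconnection fraction over it would be undefined.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    mask = np.asarray(prob_volume, dtype=float) >= threshold
    if not mask.any():
        warnings.warn("binarize_tract produced an empty mask", stacklevel=2)
    return mask


def disconnection_fraction(lesion: np.ndarray, tract: np.ndarray) -> float:
    """|lesion ∩ tract| / |tract| as a fraction in [0, 1]."""
    lesion = np.asarray(lesion, dtype=bool)
    tract = np.asarray(tract, dtype=bool)
    if lesion.shape != tract.shape:
        raise GridMismatchError(
            f"lesion grid {lesion.shape} != tract grid {tract.shape}"
        )
    n_tract = int(tract.sum())
    if n_tract == 0:
        raise ValueError("empty tract mask: disconnection fraction undefined")
    return float(np.logical_and(lesion, tract).sum()) / n_tract


def rob_fraction(
    lesion: np.ndarray,
    players: dict[str, np.ndarray],
    pool: dict[str, np.ndarray],
) -> float:
    """Lesioned share of the rest-of-brain region.

    The RoB region is the union of the pool masks minus any voxel that
    also belongs to a player tract, so overlap is never counted against
    both a player and the RoB.
    """
    if not pool:
        raise ValueError("empty pool: RoB undefined")
    lesion = np.asarray(lesion, dtype=bool)
    union = np.zeros_like(lesion, dtype=bool)
    for mask in pool.values():
        if mask.shape != lesion.shape:
            raise GridMismatchError("pool mask grid differs from lesion grid")
        union |= np.asarray(mask, dtype=bool)
    for mask in players.values():
        union &= ~np.asarray(mask, dtype=bool)
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("RoB region empty after removing player voxels")
    return float(np.logical_and(lesion, union).sum()) / n_union


def profile_patient(
    lesion: np.ndarray,
    atlas: TractAtlas,
    threshold: float = 0.5,
    patient_id: str = "",
    include_rob: bool = True,
) -> DisconnectionProfile:
    """Damaged-fraction vector for one patient over all players.

    Applies the disconnection fraction to every named tract and, when
    the atlas carries a pool, appends the RoB fraction as the final
    player.
    """
    masks = atlas.binary_masks(threshold)
    d = [disconnection_fraction(lesion, masks[name]) for name in atlas.names]
    names = list(atlas.names)
    if include_rob and atlas.pool:
        d.append(rob_fraction(lesion, masks, atlas.pool_masks(threshold)))
        names.append(ROB)
    return DisconnectionProfile(
        patient_id=patient_id, player_names=tuple(names), d=np.array(d)
    )


def profiles_to_frame(
    profiles: list[DisconnectionProfile], percent: bool = False
) -> pd.DataFrame:
    """Stack profiles into a patients x players frame (fraction or %)."""
    if not profiles:
        raise ValueError("no profiles")
    names = profiles[0].player_names
    for p in profiles:
        if p.player_names != names:
            raise ValueError("profiles carry inconsistent player sets")
    data = np.vstack([p.d for p in profiles])
    if percent:
        data = data * 100.0
    return pd.DataFrame(data, index=[p.patient_id for p in profiles], columns=list(names))


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations of per-tract damage across patients.

    ``masked`` flags entries whose two-sided p-value is >= the
    significance level; ``undefined`` lists zero-variance players whose
    rows/columns are NaN rather than silently zeroed.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    masked: pd.DataFrame
    undefined: list[str]
    level: float = 0.05


def lesion_correlation_matrix(
    profiles: list[DisconnectionProfile],
    level: float = 0.05,
    order: list[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation of damage patterns between every tract pair.

    Requires at least three profiles.  Pass ``order`` to present the
    matrix with chosen players adjacent (e.g., largest values near the
    diagonal, as lesion-covariance panels are often displayed).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for correlations")
    frame = profiles_to_frame(profiles)
    if order is not None:
        frame = frame[order]
    names = list(frame.columns)
    m = len(names)
    variances = frame.var(axis=0, ddof=1)
    undefined = [n for n in names if variances[n] == 0]
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    for i in range(m):
        if names[i] in undefined:
            continue
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, m):
            if names[j] in undefined:
                continue
            res = stats.pearsonr(frame.iloc[:, i], frame.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=names, columns=names)
    pdf = pd.DataFrame(p, index=names, columns=names)
    masked = pdf >= level
    return CorrelationResult(r=rdf, p=pdf, masked=masked, undefined=undefined, level=level)
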