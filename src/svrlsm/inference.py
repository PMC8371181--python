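"""Permutation-based family-wise error control for beta maps.

The behavioral scores are permuted across participants (lesion data
fixed), the SVR is refitted per permutation, and the k-th highest beta
over voxels is recorded for k in {1, 10, 100, 1000}. The k = 1 (maximum
statistic) null gives strict FWER control at the chosen alpha; the
larger ranks give progressively more lenient thresholds whose
significant sets are nested by construction.

Significance is assessed one-tailed in the deficit direction: the
dependent variable is oriented upstream so that a larger beta always
means a stronger lesion-deficit association. A two-tailed variant
(thresholding |beta|) is available via ``tail='two-sided'``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .estimator import SVRLSM
from .exceptions import CohortGeometryError, InvalidInputError
from .lesions import LesionMatrix

__all__ = [
    "NullDistribution",
    "ThresholdResult",
    "Cluster",
    "build_null",
    "threshold_map",
    "extract_clusters",
    "overlap_report",
    "DEFAULT_RANKS",
]

log = logging.getLogger("svrlsm")

DEFAULT_RANKS = (1, 10, 100, 1000)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class NullDistribution:
    """Per-permutation k-th highest beta values, one column per rank."""

    ranks: tuple[int, ...]
    samples: np.ndarray  # (n_permutations, n_ranks)
    n_permutations: int
    seed: int
    tail: str = "deficit"

    def for_rank(self, rank: int) -> np.ndarray:
        try:
            col = self.ranks.index(rank)
        except ValueError:
            raise InvalidInputError(
                f"rank {rank} not in null distribution (has {self.ranks})"
            ) from None
        return self.samples[:, col]

    def save(self, path) -> None:
        np.savez_compressed(
            str(path),
            samples=self.samples,
            ranks=np.array(self.ranks),
            n_permutations=self.n_permutations,
            seed=self.seed,
            tail=np.array(self.tail),
        )

    @classmethod
    def load(cls, path) -> "NullDistribution":
        with np.load(str(path), allow_pickle=False) as d:
            return cls(
                ranks=tuple(int(r) for r in d["ranks"]),
                samples=d["samples"],
                n_permutations=int(d["n_permutations"]),
                seed=int(d["seed"]),
                tail=str(d["tail"]),
            )


@dataclass
class ThresholdResult:
    """A thresholded beta map at one null rank."""

    rank: int
    alpha: float
    threshold_value: float
    significant: np.ndarray  # boolean per included voxel
    tail: str = "deficit"

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass
class Cluster:
    """A connected component of significant voxels."""

    id: int
    voxel_count: int
    volume_mm3: float
    centroid_world_mm: tuple[float, float, float]
    peak_beta: float
    peak_world_mm: tuple[float, float, float]
    atlas_label: str | None = None


def _ranked_stats(beta: np.ndarray, ranks: tuple[int, ...], tail: str) -> np.ndarray:
    values = np.abs(beta) if tail == "two-sided" else beta
    # k-th highest via partial sort
    out = np.empty(len(ranks))
    srt = np.sort(values)[::-1]
    for idx, k in enumerate(ranks):
        out[idx] = srt[k - 1]
    return out


def build_null(
    X: np.ndarray | LesionMatrix,
    y: np.ndarray,
    model: SVRLSM | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    ranks: tuple[int, ...] = DEFAULT_RANKS,
    tail: str = "deficit",
    raw: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullDistribution:
    """Permutation null of the k-th highest beta for each requested rank.

    Per permutation the behavioral vector (already residualized, so the
    covariate adjustment travels with it) is shuffled across
    participants, the SVR refitted, and the ranked maxima of the beta
    map recorded. Passing ``raw=(y_raw, covariates)`` instead permutes
    the raw scores and re-residualizes within each permutation. The
    kernel Gram matrix depends only on the lesion data and is computed
    once, which keeps 5,000 refits tractable. Fully reproducible from
    the seed.
    """
    if n_perm < 100:
        raise InvalidInputError("need at least 100 permutations")
    Xarr = X.X if isinstance(X, LesionMatrix) else np.asarray(X)
    Xarr = np.asarray(Xarr, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Xarr.shape[0] != y.size:
        raise InvalidInputError("X rows and y length differ")
    model = model if model is not None else SVRLSM()
    n_vox = Xarr.shape[1]
    kept = tuple(r for r in ranks if r <= n_vox)
    for r in ranks:
        if r > n_vox:
            warnings.warn(
                f"rank {r} exceeds the {n_vox}-voxel map; skipped", stacklevel=2
            )
    if not kept:
        raise InvalidInputError("no requested rank fits within the voxel count")
    gram = model.gram(Xarr)
    Xp = model._prepare(Xarr)
    rng = np.random.default_rng(seed)
    samples = np.empty((n_perm, len(kept)))
    if raw is not None:
        from .estimator import residualize

        y_raw, covariates = raw
        y_raw = np.asarray(y_raw, dtype=float).ravel()
        for p in range(n_perm):
            y_perm = residualize(rng.permutation(y_raw), covariates)
            beta = model.fit_permuted_beta(gram, Xp, y_perm)
            samples[p] = _ranked_stats(beta, kept, tail)
    else:
        for p in range(n_perm):
            beta = model.fit_permuted_beta(gram, Xp, rng.permutation(y))
            samples[p] = _ranked_stats(beta, kept, tail)
    if log.isEnabledFor(logging.DEBUG):
        for p in range(n_perm):
            log.debug("permutation %d: ranked betas %s", p, samples[p])
    return NullDistribution(kept, samples, n_perm, seed, tail)


def threshold_map(
    beta: np.ndarray,
    null: NullDistribution,
    rank: int = 1,
    alpha: float = 0.05,
) -> ThresholdResult:
    """Threshold a beta map against the permutation null at one rank.

    The critical value is the ceil((1 - alpha) * n_perm)-th smallest
    null sample (an empirical order statistic); voxels strictly above
    it are significant, so ties with the threshold are resolved
    conservatively.
    """
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    samples = np.sort(null.for_rank(rank))
    idx = math.ceil((1 - alpha) * null.n_permutations) - 1
    thresh = float(samples[idx])
    values = np.abs(beta) if null.tail == "two-sided" else np.asarray(beta)
    return ThresholdResult(rank, alpha, thresh, values > thresh, null.tail)


def extract_clusters(
    result: ThresholdResult,
    beta: np.ndarray,
    matrix: LesionMatrix,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of the significant voxel set.

    Components are found under the requested 3D connectivity (6, 18 or
    26 neighbors), measured in voxels and mm^3, located by world-space
    centroid and peak beta, and returned sorted by volume descending.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidInputError("connectivity must be 6, 18 or 26")
    sig_volume = matrix.to_volume(result.significant.astype(float)) > 0.5
    labels, n_clusters = ndimage.label(sig_volume, structure=_STRUCTURES[connectivity])
    if n_clusters == 0:
        return []
    beta_volume = matrix.to_volume(np.asarray(beta, dtype=float))
    voxel_mm3 = float(np.prod(matrix.voxel_dims))
    clusters = []
    for lab in range(1, n_clusters + 1):
        coords = np.argwhere(labels == lab)
        betas = beta_volume[tuple(coords.T)]
        peak_local = coords[np.argmax(betas)]
        centroid_vox = coords.mean(axis=0)
        clusters.append(
            Cluster(
                id=lab,
                voxel_count=len(coords),
                volume_mm3=len(coords) * voxel_mm3,
                centroid_world_mm=tuple(_to_world(matrix.affine, centroid_vox)),
                peak_beta=float(betas.max()),
                peak_world_mm=tuple(_to_world(matrix.affine, peak_local)),
            )
        )
    clusters.sort(key=lambda c: (-c.voxel_count, c.id))
    for new_id, c in enumerate(clusters, start=1):
        c.id = new_id
    return clusters


def _to_world(affine: np.ndarray, voxel_coord: np.ndarray) -> np.ndarray:
    return (affine @ np.append(voxel_coord, 1.0))[:3]


def label_clusters(clusters, atlas_grid, atlas_affine, names, matrix) -> None:
    """Attach atlas labels from a user-supplied integer-labeled volume.

    The atlas must share the cohort grid; ``names`` maps integer codes
    to region names. Labels are read at each cluster's peak voxel.
    """
    atlas_grid = np.asarray(atlas_grid)
    if atlas_grid.shape != matrix.inclusion_mask.shape or not np.allclose(
        atlas_affine, matrix.affine, atol=1e-6
    ):
        raise CohortGeometryError("atlas volume is not on the cohort grid")
    inv = np.linalg.inv(atlas_affine)
    for c in clusters:
        vox = np.round((inv @ np.append(c.peak_world_mm, 1.0))[:3]).astype(int)
        code = int(atlas_grid[tuple(vox)])
        c.atlas_label = names.get(code, f"label {code}")


def overlap_report(a: ThresholdResult, b: ThresholdResult) -> dict[str, int]:
    """Voxel counts in a only, b only, and both, by exact set arithmetic."""
    if a.significant.shape != b.significant.shape:
        raise CohortGeometryError("threshold results cover different voxel sets")
    both = a.significant & b.significant
    return {
        "a_only": int((a.significant & ~b.significant).sum()),
        "b_only": int((b.significant & ~a.significant).sum()),
        "both": int(both.sum()),
        "a_total": int(a.significant.sum()),
        "b_total": int(b.significant.sum()),
    }
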