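"""Sammon mapping of CSSC matrices into the plane.

Sammon's stress weights each pairwise term by the inverse of the original
distance, so small original distances must be preserved accurately:

    E = (1 / sum_{i<j} d_ij) * sum_{i<j} (d_ij - e_ij)^2 / d_ij

with d_ij the original-space and e_ij the image-space Euclidean distances.
For binary CSSC columns the Euclidean distance is the square root of the
Hamming distance, so the map is monotone in symptom disagreement counts.

Coordinates are initialized from PCA (deterministic sign convention) and
refined by Sammon's diagonal-Newton gradient iteration with step halving, so
the accepted stress trace is non-increasing.  Duplicate input columns are
collapsed before optimization (the stress is undefined at zero original
distance) and share one output point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .criteria import CriteriaError
from .enumeration import CSSCSet
from .similarity import embed_shared

__all__ = ["ProjectionResult", "sammon", "project_pair", "sammon_stress"]


@dataclass(frozen=True)
class ProjectionResult:
    """2-D coordinates per distinct input vector, with the stress trace.

    ``column_to_point[j]`` gives the point index of input column ``j``;
    duplicate columns share a point.  ``stress`` is Sammon's E recomputed
    from the final coordinates.
    """

    coordinates: np.ndarray  # (n_points, 2)
    stress: float
    stress_trace: tuple[float, ...]
    column_to_point: tuple[int, ...]
    n_iter: int
    converged: bool


def sammon_stress(original_d: np.ndarray, coords: np.ndarray) -> float:
    """Sammon's stress E of an embedding, from condensed original distances."""
    img = pdist(coords)
    c = original_d.sum()
    return float(((original_d - img) ** 2 / original_d).sum() / c)


def _unique_columns(matrix: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    cols = np.asarray(matrix).T
    seen: dict[bytes, int] = {}
    uniques = []
    inverse = []
    for col in cols:
        key = np.ascontiguousarray(col).tobytes()
        if key not in seen:
            seen[key] = len(uniques)
            uniques.append(col)
        inverse.append(seen[key])
    return np.array(uniques, dtype=float), tuple(inverse)


def _pca_init(points: np.ndarray, dims: int, rng: np.random.Generator) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Deterministic sign: make each component's largest-magnitude loading positive.
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    coords = centered @ vt[:dims].T
    if coords.shape[1] < dims:
        coords = np.hstack(
            [coords, np.zeros((coords.shape[0], dims - coords.shape[1]))]
        )
    # Break exact coincidences in the image (possible when points differ only
    # along discarded components); the stress gradient needs e_ij > 0.
    if np.any(pdist(coords) == 0):
        coords = coords + 1e-4 * rng.standard_normal(coords.shape)
    return coords


def sammon(
    matrix: np.ndarray,
    *,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    step: float = 0.35,
    seed: int | None = 0,
) -> ProjectionResult:
    """Project the columns of a binary matrix into ``dims`` dimensions.

    ``matrix`` has one row per symptom and one column per CSSC (the matrix
    orientation used throughout the package).  Requires at least three
    distinct columns.  Deterministic given ``seed`` and inputs.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise CriteriaError("expected a 2-D matrix (rows = symptoms)")
    points, inverse = _unique_columns(matrix)
    n = points.shape[0]
    if n < 3:
        raise CriteriaError(
            f"Sammon projection needs >= 3 distinct columns, got {n}"
        )
    rng = np.random.default_rng(seed)
    orig = pdist(points)
    if np.any(orig == 0):  # cannot happen after dedup, kept as a guard
        raise CriteriaError("zero original distance between distinct columns")
    c = orig.sum()
    d_full = squareform(orig)

    y = _pca_init(points, dims, rng)
    trace = [sammon_stress(orig, y)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        e_full = squareform(pdist(y))
        np.fill_diagonal(e_full, 1.0)
        np.fill_diagonal(d_full, 1.0)

        delta = d_full - e_full
        de = d_full * e_full
        one = delta / de
        np.fill_diagonal(one, 0.0)

        diff = y[:, None, :] - y[None, :, :]  # (n, n, dims)
        grad = (-2.0 / c) * (one[:, :, None] * diff).sum(axis=1)

        d2 = diff ** 2
        delta3 = delta[:, :, None]
        e3 = e_full[:, :, None]
        hess_term = (delta3 - (d2 / e3) * (1.0 + delta3 / e3)) / de[:, :, None]
        # zero self terms
        idx = np.arange(n)
        hess_term[idx, idx, :] = 0.0
        hess = (-2.0 / c) * hess_term.sum(axis=1)

        denom = np.abs(hess)
        denom[denom < 1e-12] = 1e-12
        direction = -grad / denom

        prev = trace[-1]
        alpha = step
        accepted = False
        for _ in range(40):
            cand = y + alpha * direction
            if np.any(pdist(cand) == 0):
                alpha *= 0.5
                continue
            stress = sammon_stress(orig, cand)
            if stress <= prev:
                y = cand
                trace.append(stress)
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = True
            break
        if prev - trace[-1] <= tol * max(prev, 1e-30):
            converged = True
            break

    final = sammon_stress(orig, y)
    return ProjectionResult(
        coordinates=y,
        stress=final,
        stress_trace=tuple(trace),
        column_to_point=inverse,
        n_iter=it,
        converged=converged,
    )


def project_pair(
    a: CSSCSet,
    b: CSSCSet,
    **params,
) -> tuple[ProjectionResult, tuple[tuple[str, ...], ...]]:
    """Project the combined CSSCs of two disorders into the plane.

    The two sets are embedded in their shared symptom space and their columns
    concatenated.  Returns the projection plus, per point, the sorted tuple
    of disorder names owning that vector; a CSSC shared by both disorders is
    labeled with both.
    """
    pair = embed_shared(a, b)
    combined = np.hstack([pair.a, pair.b])
    result = sammon(combined, **params)
    owners: dict[int, set[str]] = {}
    m = pair.a.shape[1]
    for j, p in enumerate(result.column_to_point):
        owners.setdefault(p, set()).add(pair.a_name if j < m else pair.b_name)
    labels = tuple(
        tuple(sorted(owners[p])) for p in range(result.coordinates.shape[0])
    )
    return result, labels
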