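"""Conceptual relatedness of disorders via Maximum Pairwise Cosine Similarity.

Each disorder is represented by the binary matrix of its weakly irredundant
CSSCs embedded in a shared symptom space (irrelevant symptoms encoded as 0).
For every CSSC of one disorder we take its best cosine match among the CSSCs
of the other; the per-column best matches are aggregated by max or mean in
each direction, and the final MPCS is the larger of the two directional
aggregates:

    S_MC(A_i, B) = max_j S_C(A_i, B_j)
    phi_max(A, B) = max_i S_MC(A_i, B)      phi_mean(A, B) = mean_i S_MC(A_i, B)
    MPCS_max = max(phi_max(A,B), phi_max(B,A))
    MPCS_mean = max(phi_mean(A,B), phi_mean(B,A))

so that 0 <= MPCS_mean <= MPCS_max <= 1 always holds.  MPCS_max = 1 exactly
when the two disorders share an identical weakly irredundant CSSC (a
no-overlap violation); MPCS_max = 0 exactly when their relevant symptom sets
are disjoint.

Cosines are computed from integer counts — shared ones over the geometric
mean of the column weights — so each value is exact up to a single square
root.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Sequence

import numpy as np

from .criteria import CriteriaError, SymptomUniverse
from .enumeration import CSSCSet

__all__ = [
    "EmbeddedPair",
    "SimilarityResult",
    "cosine_binary",
    "embed_shared",
    "mpcs",
    "mpcs_matrix",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, matching printed report precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cosine_binary(u: Sequence[int], v: Sequence[int]) -> float:
    """Cosine similarity of two binary vectors from integer counts.

    Equals |support(u) ∩ support(v)| / sqrt(|support(u)| · |support(v)|);
    raises on a zero vector (undefined norm) or length mismatch.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise CriteriaError("vectors must be 1-D and of equal length")
    nu = int(np.count_nonzero(u))
    nv = int(np.count_nonzero(v))
    if nu == 0 or nv == 0:
        raise CriteriaError("cosine similarity undefined for a zero vector")
    shared = int(np.count_nonzero(np.logical_and(u != 0, v != 0)))
    return shared / sqrt(nu * nv)


@dataclass(frozen=True)
class EmbeddedPair:
    """Two CSSC matrices over the same shared symptom order ('?' -> 0)."""

    symptoms: tuple[str, ...]
    a_name: str
    b_name: str
    a: np.ndarray  # n x m, int8
    b: np.ndarray  # n x l, int8


def embed_shared(a: CSSCSet, b: CSSCSet) -> EmbeddedPair:
    """Embed two CSSC sets in their shared symptom space.

    The shared order is the sorted union of the two relevant symptom sets;
    symptoms irrelevant to (or absent from) one disorder appear as 0 rows in
    its matrix.  Symptoms irrelevant to both are dropped — they are zero in
    every column and cannot affect any cosine.
    """
    shared = sorted(a.relevant | b.relevant)
    idx = {s: i for i, s in enumerate(shared)}

    def matrix(cs: CSSCSet) -> np.ndarray:
        m = np.zeros((len(shared), len(cs.combinations)), dtype=np.int8)
        for j, combo in enumerate(cs.combinations):
            for s in combo:
                m[idx[s], j] = 1
        return m

    return EmbeddedPair(tuple(shared), a.name, b.name, matrix(a), matrix(b))


@dataclass(frozen=True)
class SimilarityResult:
    """Directional best-match cosines and their MPCS aggregates for a pair."""

    a_name: str
    b_name: str
    smc_ab: tuple[float, ...]  # best match of each A column within B
    smc_ba: tuple[float, ...]
    phi_max_ab: float
    phi_mean_ab: float
    phi_max_ba: float
    phi_mean_ba: float
    mpcs_max: float
    mpcs_mean: float

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "mpcs_max": round_half_up(self.mpcs_max, ndigits),
            "mpcs_mean": round_half_up(self.mpcs_mean, ndigits),
        }


def _pairwise_cosines(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """m x l matrix of binary cosines between columns of a and b."""
    a = a.astype(np.int64)
    b = b.astype(np.int64)
    wa = a.sum(axis=0)
    wb = b.sum(axis=0)
    if np.any(wa == 0) or np.any(wb == 0):
        raise CriteriaError("all-zero CSSC column: cosine undefined")
    shared = a.T @ b
    return shared / np.sqrt(np.outer(wa, wb))


def mpcs(a: CSSCSet, b: CSSCSet) -> SimilarityResult:
    """Maximum Pairwise Cosine Similarity between two disorders' CSSC sets."""
    if len(a) == 0 or len(b) == 0:
        raise CriteriaError("MPCS requires non-empty CSSC sets")
    pair = embed_shared(a, b)
    cos = _pairwise_cosines(pair.a, pair.b)
    smc_ab = cos.max(axis=1)
    smc_ba = cos.max(axis=0)
    phi_max_ab = float(smc_ab.max())
    phi_mean_ab = float(smc_ab.mean())
    phi_max_ba = float(smc_ba.max())
    phi_mean_ba = float(smc_ba.mean())
    return SimilarityResult(
        a.name,
        b.name,
        tuple(float(x) for x in smc_ab),
        tuple(float(x) for x in smc_ba),
        phi_max_ab,
        phi_mean_ab,
        phi_max_ba,
        phi_mean_ba,
        mpcs_max=max(phi_max_ab, phi_max_ba),
        mpcs_mean=max(phi_mean_ab, phi_mean_ba),
    )


def mpcs_matrix(
    disorders: Sequence[CSSCSet], statistic: str = "mean"
) -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric pairwise MPCS matrix (unit diagonal) over >= 2 disorders.

    Returns the disorder name order and a float matrix; render with
    :func:`round_half_up` for reports.
    """
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")
    if len(disorders) < 2:
        raise CriteriaError("mpcs_matrix needs at least two disorders")
    names = tuple(d.name for d in disorders)
    n = len(disorders)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = mpcs(disorders[i], disorders[j])
            out[i, j] = out[j, i] = r.mpcs_max if statistic == "max" else r.mpcs_mean
    return names, out
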