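"""Meta-profile construction and blur-kernel estimation.

Blur kernels describe the probability that imperfect nuclease digestion moves
an observed 5' read end away from the true footprint boundary.  They are
estimated per read length from start-codon-anchored meta-profiles with an
EM-like loop in which a non-negative least-squares kernel update precedes the
ridge-damped deviation update.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.sparse.linalg import lsqr

from ribodeconv.profiles import (
    ANCHOR_LENGTH,
    L_UP_DEFAULT,
    LengthProfile,
    TranscriptAnnotation,
)

logger = logging.getLogger(__name__)

#: blur kernels span offsets [-15, 15] -- about half a ribosome either way
BLUR_HALF_WIDTH = 15
BLUR_WIDTH = 2 * BLUR_HALF_WIDTH + 1

#: meta-profiles keep the first 350 positions downstream of the start codon
META_DOWNSTREAM = 350

#: minimum transcript length for meta-profile inclusion (boundary effects)
META_MIN_TRANSCRIPT_LENGTH = 350

#: fraction of meta-profile positions masked as outliers (top 5% of in-frame
#: reads, i.e. one third of positions, gives 0.05 / 3 ~ 1.65% of positions)
OUTLIER_FRACTION = 0.0165


@dataclass
class BlurVector:
    """Non-negative digestion-offset weights over ``[-15, 15]`` for one length."""

    read_length: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (BLUR_WIDTH,):
            raise ValueError(f"blur vector must have {BLUR_WIDTH} weights")
        if np.any(self.weights < 0):
            raise ValueError("blur weights must be non-negative")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-BLUR_HALF_WIDTH, BLUR_HALF_WIDTH + 1)

    def normalized(self) -> "BlurVector":
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero blur vector")
        return BlurVector(self.read_length, self.weights / total)


def delta_blur(read_length: int, offset: int = 0) -> BlurVector:
    """A kernel concentrating all mass at a single digestion offset."""
    w = np.zeros(BLUR_WIDTH)
    w[offset + BLUR_HALF_WIDTH] = 1.0
    return BlurVector(read_length, w)


@dataclass
class MetaProfile:
    """Summed 5'-end counts across transcripts for one read length.

    ``values[i]`` is anchored at position ``i - l_up`` relative to the start
    codon; masked positions are ignored by all fitting.
    """

    read_length: int
    values: np.ndarray
    outlier_mask: np.ndarray
    l_up: int = L_UP_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.values.shape != self.outlier_mask.shape:
            raise ValueError("values and outlier_mask must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("meta-profile values must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.values.size) - self.l_up


def _conv_matrix(weights: np.ndarray, n: int) -> np.ndarray:
    """Dense n-by-n convolution matrix: ``A[i, t] = w[i - t]``."""
    A = np.zeros((n, n))
    for j in range(-BLUR_HALF_WIDTH, BLUR_HALF_WIDTH + 1):
        w = weights[j + BLUR_HALF_WIDTH]
        if w != 0.0:
            A += w * np.eye(n, k=-j)
    return A


def build_meta_profile(
    profiles: list[LengthProfile],
    read_length: int,
    annotations: dict[str, TranscriptAnnotation],
    l_up: int = L_UP_DEFAULT,
    downstream: int = META_DOWNSTREAM,
    min_transcript_length: int = META_MIN_TRANSCRIPT_LENGTH,
    outlier_fraction: float = OUTLIER_FRACTION,
) -> MetaProfile:
    """Accumulate 5'-end counts of one read length across long transcripts.

    Only transcripts longer than ``min_transcript_length`` contribute (this
    limits convolution boundary effects); the window spans
    ``[-l_up, downstream)``.  The ``ceil(outlier_fraction * n)`` positions
    with the highest summed counts are masked as outliers.
    """
    n = l_up + downstream
    values = np.zeros(n)
    used = 0
    for p in profiles:
        if p.read_length != read_length:
            continue
        annot = annotations[p.transcript_id]
        if annot.length <= min_transcript_length:
            continue
        used += 1
        m = min(p.counts.size, n)
        values[:m] += p.counts[:m]
    if used == 0:
        raise ValueError(
            f"no transcript longer than {min_transcript_length} nt contributes "
            f"to the length-{read_length} meta-profile"
        )
    n_mask = math.ceil(outlier_fraction * n)
    mask = np.zeros(n, dtype=bool)
    if n_mask > 0:
        top = np.argsort(values, kind="stable")[::-1][:n_mask]
        mask[top] = True
    return MetaProfile(read_length, values, mask, l_up=l_up)


def fit_blur(m_true_shifted: np.ndarray, m_obs: MetaProfile) -> BlurVector:
    """Non-negative least-squares kernel fit for one read length.

    The design-matrix column for offset ``j`` is the (already shifted)
    consensus meta-profile shifted by a further ``j`` cells with zero padding;
    masked positions are excluded from the residual.  The NNLS solution is
    normalized to sum 1.
    """
    from ribodeconv.deblur import shift_profile

    m_true_shifted = np.asarray(m_true_shifted, dtype=float)
    if not np.any(m_true_shifted):
        raise ValueError("all-zero consensus meta-profile")
    n = m_true_shifted.size
    design = np.empty((n, BLUR_WIDTH))
    for j in range(-BLUR_HALF_WIDTH, BLUR_HALF_WIDTH + 1):
        design[:, j + BLUR_HALF_WIDTH] = shift_profile(m_true_shifted, j)
    rows = ~m_obs.outlier_mask
    weights, _ = nnls(design[rows], m_obs.values[rows])
    return BlurVector(m_obs.read_length, weights).normalized()


@dataclass
class BlurFit:
    """Result of the meta-profile EM: kernels plus diagnostics."""

    blurs: dict[int, BlurVector]
    meta_consensus: np.ndarray
    objective_trace: list[float]
    converged: bool


def estimate_all_blurs(
    meta: dict[int, MetaProfile] | list[MetaProfile],
    tol: float = 0.01,
    max_iter: int = 100,
) -> BlurFit:
    """EM-like blur estimation over all read lengths.

    The meta-consensus is initialized from the in-frame cells of the
    length-28 meta-profile.  Each round re-fits every kernel with NNLS,
    solves the ridge-damped (damp=1) deviation update per length, and then
    replaces the consensus with the weighted average of the per-length
    signals (clip negatives, renormalize).  Stops when the relative objective
    change drops below ``tol``.
    """
    from ribodeconv.deblur import shift_profile

    if not isinstance(meta, dict):
        meta = {m.read_length: m for m in meta}
    if ANCHOR_LENGTH not in meta:
        raise ValueError(f"meta-profiles must include length {ANCHOR_LENGTH}")
    lengths = sorted(meta)
    n = meta[lengths[0]].values.size
    l_up = meta[lengths[0]].l_up

    # masked cells are ignored by all fitting: they are excluded from the
    # normalization scale/weights and never read as data (see init below)
    norm_obs: dict[int, np.ndarray] = {}
    weights_l: dict[int, float] = {}
    for l, m in meta.items():
        if m.values.size != n:
            raise ValueError("meta-profiles must share one window")
        total = m.values[~m.outlier_mask].sum()
        if total <= 0:
            raise ValueError(f"length-{l} meta-profile is empty")
        norm_obs[l] = m.values / total
        weights_l[l] = float(total)

    positions = np.arange(n) - l_up
    # masked cells hold outliers (or garbage): winsorize them to the largest
    # unmasked value so the init keeps a strong, mask-independent anchor there
    anchor = meta[ANCHOR_LENGTH]
    init_values = norm_obs[ANCHOR_LENGTH].copy()
    unmasked_max = init_values[~anchor.outlier_mask].max(initial=0.0)
    init_values[anchor.outlier_mask] = unmasked_max
    consensus = np.where(positions % 3 == 0, init_values, 0.0)
    if consensus.sum() <= 0:
        raise ValueError("length-28 meta-profile has no in-frame mass")
    consensus = consensus / consensus.sum()

    blurs: dict[int, BlurVector] = {}
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        # consensus frame -> native length-l frame is a shift by -k_l
        shifted = {l: shift_profile(consensus, ANCHOR_LENGTH - l) for l in lengths}
        blurs = {l: fit_blur(shifted[l], meta[l]) for l in lengths}
        # ridge-damped deviation update per length, masked rows excluded
        deviations: dict[int, np.ndarray] = {}
        obj = 0.0
        for l in lengths:
            A = _conv_matrix(blurs[l].weights, n)
            rows = ~meta[l].outlier_mask
            resid = A @ shifted[l] - norm_obs[l]
            eps = lsqr(
                A[rows], resid[rows], damp=1.0, atol=1e-12, btol=1e-12,
                iter_lim=10 * n + 100,
            )[0]
            deviations[l] = eps
            fit_resid = (A @ (shifted[l] - eps) - norm_obs[l])[rows]
            obj += weights_l[l] * (fit_resid @ fit_resid + eps @ eps)
        trace.append(float(obj))
        # consensus update: weighted average of per-length signals
        delta = np.zeros(n)
        for l in lengths:
            delta += weights_l[l] * shift_profile(deviations[l], l - ANCHOR_LENGTH)
        consensus = consensus - delta / sum(weights_l.values())
        consensus = np.clip(consensus, 0.0, None)
        if consensus.sum() <= 0:
            raise ValueError("meta-consensus annihilated during blur estimation")
        consensus = consensus / consensus.sum()
        if it > 0 and trace[-2] > 0 and abs(trace[-1] - trace[-2]) / trace[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("blur estimation did not converge in %d rounds", max_iter)
    return BlurFit(blurs=blurs, meta_consensus=consensus, objective_trace=trace, converged=converged)
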