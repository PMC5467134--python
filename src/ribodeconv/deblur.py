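"""EM-like total-least-squares deconvolution of length-stratified profiles.

The hidden consensus position signal lives on the 5'-end coordinate frame of
length-28 reads.  An observed profile of length ``l`` is aligned onto that
frame by shifting it right by ``k_l = l - 28`` (the 3-nt periodicity of
length-``l`` pileups starts at ``-l + 16``, so the inter-length offset is
exactly ``k_l``).  The model for each length is

    P_obs(l) = b(l) * (consensus - eps(l)) + noise

where ``*`` is discrete convolution with the 31-tap blur kernel ``b(l)`` and
``eps(l)`` is a per-length deviation field.  The M-step solves a ridge-damped
least squares for ``eps(l)`` (LSQR, damp=1); the E-step replaces the
consensus by the alpha-weighted average of the per-length signals, clips
negatives and renormalizes to sum 1.

All internal algebra is carried out on the consensus frame: observed profiles
are aligned once up front, so the per-length subproblems are plain (unshifted)
ridge problems and the E-step average is the exact minimizer of its
subproblem, which makes the objective non-increasing across every M-step and
every pre-clipping E-step.  Deviations are therefore stored on the consensus
frame; reported per-length signals are shifted back to their native frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, lsqr

from ribodeconv.metablur import BlurVector, BLUR_HALF_WIDTH
from ribodeconv.profiles import ANCHOR_LENGTH, LengthProfile, ProfileSet, normalize_profile

logger = logging.getLogger(__name__)

_LSQR_TOL = 1e-12


@dataclass
class ConsensusSignal:
    """Non-negative, sum-to-1 hidden position signal on the 28-nt 5' frame."""

    transcript_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("consensus must be non-negative")
        total = self.values.sum()
        if total > 0 and not np.isclose(total, 1.0):
            raise ValueError("consensus must sum to 1")


@dataclass
class DeviationField:
    """Per-length deviation of the consensus, on the consensus frame."""

    read_length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("deviation field contains non-finite entries")


@dataclass
class DeblurResult:
    """Outcome of deconvolving one transcript.

    ``per_length`` maps read length to ``(p_true, k_l, alpha)`` where
    ``p_true`` is the recovered length-specific signal on its native 5'-end
    frame (negatives clipped at reporting time).  ``trace`` holds one dict per
    EM round with the objective before the M-step, after the M-step, and after
    the pre-clipping E-step.
    """

    transcript_id: str
    consensus: ConsensusSignal
    per_length: dict[int, tuple[np.ndarray, int, float]]
    deviations: dict[int, DeviationField]
    objective_trace: list[float]
    converged: bool
    trace: list[dict] = field(default_factory=list)


def shift_for_length(read_length: int) -> int:
    """Alignment shift ``k_l = l - 28`` onto the length-28 coordinate frame."""
    return read_length - ANCHOR_LENGTH


def convolve(signal: np.ndarray, blur: BlurVector | np.ndarray) -> np.ndarray:
    """Blur a signal: ``out[i] = sum_j b[j] * signal[i - j]``, zero padded.

    The output has the same length as the input; mass leaving the window is
    dropped (zero-padding boundary).
    """
    weights = blur.weights if isinstance(blur, BlurVector) else np.asarray(blur, float)
    if weights.size != 2 * BLUR_HALF_WIDTH + 1:
        raise ValueError(f"blur must have {2 * BLUR_HALF_WIDTH + 1} weights")
    signal = np.asarray(signal, dtype=float)
    full = np.convolve(signal, weights, mode="full")
    return full[BLUR_HALF_WIDTH : BLUR_HALF_WIDTH + signal.size]


def correlate(signal: np.ndarray, blur: BlurVector | np.ndarray) -> np.ndarray:
    """Adjoint of :func:`convolve` (cross-correlation with the kernel)."""
    weights = blur.weights if isinstance(blur, BlurVector) else np.asarray(blur, float)
    full = np.convolve(np.asarray(signal, float), weights[::-1], mode="full")
    return full[BLUR_HALF_WIDTH : BLUR_HALF_WIDTH + signal.size]


def shift_profile(v: np.ndarray, k: int) -> np.ndarray:
    """Shift right by ``k`` (left for negative ``k``) with zero fill."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    n = v.size
    if k >= 0:
        out[k:] = v[: n - k]
    else:
        out[: n + k] = v[-k:]
    return out


def blur_operator(blur: BlurVector | np.ndarray, n: int) -> LinearOperator:
    """The n-by-n convolution operator for a blur kernel."""
    return LinearOperator(
        (n, n),
        matvec=lambda x: convolve(x, blur),
        rmatvec=lambda y: correlate(y, blur),
    )


def init_consensus(p28: LengthProfile) -> ConsensusSignal:
    """Initial consensus: in-frame (frame-0) cells of the length-28 pileup.

    Off-frame cells are zeroed and the result is renormalized to sum 1.
    """
    in_frame = np.where(np.mod(p28.positions, 3) == 0, p28.counts, 0.0)
    total = in_frame.sum()
    if total <= 0:
        raise ValueError(
            f"{p28.transcript_id}: no in-frame mass to initialize the consensus"
        )
    return ConsensusSignal(p28.transcript_id, in_frame / total)


def aligned_counts(p: LengthProfile, normalized: bool = True) -> np.ndarray:
    """Observed counts shifted onto the consensus (length-28) frame."""
    counts = normalize_profile(p).counts if normalized else p.counts
    return shift_profile(counts, shift_for_length(p.read_length))


def m_step(
    consensus: ConsensusSignal, p: LengthProfile, b: BlurVector
) -> DeviationField:
    """Solve the ridge-damped deviation subproblem for one read length.

    Minimizes ``||b * eps - (b * consensus - q)||^2 + ||eps||^2`` where ``q``
    is the observed profile aligned onto the consensus frame, using LSQR with
    ``damp=1``.  Deviations for different lengths are independent.  ``p`` is
    expected to be normalized already (see :func:`normalize_profile`); its
    counts are used as given so that callers control the scale.
    """
    if p.read_length != b.read_length:
        raise ValueError("blur vector is for a different read length")
    q = aligned_counts(p, normalized=False)
    n = consensus.values.size
    if q.size != n:
        raise ValueError(
            f"dimension mismatch: profile has {q.size} cells, consensus {n}"
        )
    r = convolve(consensus.values, b) - q
    A = blur_operator(b, n)
    eps = lsqr(
        A, r, damp=1.0, atol=_LSQR_TOL, btol=_LSQR_TOL, iter_lim=10 * n + 100
    )[0]
    return DeviationField(p.read_length, eps)


def e_step(
    consensus: ConsensusSignal,
    deviations: dict[int, DeviationField],
    alphas: dict[int, float],
    return_preclip: bool = False,
):
    """Update the consensus to the weighted average of per-length signals.

    ``P' = P - sum_l alpha(l) eps(l) / sum_l alpha(l)``; negative entries are
    clipped to zero and the result renormalized to sum 1.
    """
    total_alpha = float(sum(alphas.values()))
    if total_alpha <= 0:
        raise ValueError("total read count is zero")
    delta = np.zeros_like(consensus.values)
    for l, dev in deviations.items():
        delta += alphas[l] * dev.values
    preclip = consensus.values - delta / total_alpha
    clipped = np.clip(preclip, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("signal annihilated: consensus is all-zero after clipping")
    updated = ConsensusSignal(consensus.transcript_id, clipped / total)
    if return_preclip:
        return updated, preclip
    return updated


def objective(
    consensus: ConsensusSignal | np.ndarray,
    deviations: dict[int, DeviationField],
    profiles: dict[int, LengthProfile],
    blurs: dict[int, BlurVector],
) -> float:
    """Total weighted misfit plus deviation penalty.

    ``sum_l alpha(l) [ ||q_l - b(l) * (consensus - eps(l))||^2 +
    ||eps(l)||^2 ]`` with ``q_l`` the aligned observed profile.
    """
    values = consensus.values if isinstance(consensus, ConsensusSignal) else np.asarray(consensus, float)
    total = 0.0
    for l, p in profiles.items():
        eps = deviations[l].values if l in deviations else np.zeros_like(values)
        q = aligned_counts(p, normalized=False)
        resid = q - convolve(values - eps, blurs[l])
        total += p.alpha * (resid @ resid + eps @ eps)
    return float(total)


def _initial_consensus(ps: ProfileSet) -> ConsensusSignal:
    if ANCHOR_LENGTH in ps.profiles:
        return init_consensus(ps.profiles[ANCHOR_LENGTH])
    # Fallback: anchor length missing after filtering; use the most abundant
    # length aligned onto the consensus frame.
    best = max(ps.profiles.values(), key=lambda p: p.alpha)
    logger.info(
        "%s: length %d absent, initializing from length %d",
        ps.transcript_id, ANCHOR_LENGTH, best.read_length,
    )
    aligned = shift_profile(best.counts, shift_for_length(best.read_length))
    positions = np.arange(aligned.size) - best.l_up
    in_frame = np.where(positions % 3 == 0, aligned, 0.0)
    total = in_frame.sum()
    if total <= 0:
        raise ValueError(f"{ps.transcript_id}: no in-frame mass to initialize")
    return ConsensusSignal(ps.transcript_id, in_frame / total)


def deblur_transcript(
    ps: ProfileSet,
    blurs: dict[int, BlurVector],
    tol: float = 0.01,
    max_iter: int = 100,
) -> DeblurResult:
    """Run the alternating M-step / E-step deconvolution for one transcript.

    Stops when the relative change of the objective between consecutive
    rounds drops below ``tol``.  Per-length observed profiles are normalized
    to sum 1 internally; their raw totals ``alpha(l)`` act as weights.
    """
    lengths = ps.read_lengths
    profiles = {l: normalize_profile(ps.profiles[l]) for l in lengths}
    alphas = {l: ps.profiles[l].alpha for l in lengths}
    blurs = {l: blurs[l] for l in lengths}
    consensus = _initial_consensus(ps)

    deviations: dict[int, DeviationField] = {}
    objective_trace: list[float] = []
    trace: list[dict] = []
    converged = False
    for it in range(max_iter):
        pre_m = objective(consensus, deviations, profiles, blurs)
        deviations = {l: m_step(consensus, profiles[l], blurs[l]) for l in lengths}
        post_m = objective(consensus, deviations, profiles, blurs)
        updated, preclip = e_step(consensus, deviations, alphas, return_preclip=True)
        # Objective at the pre-clipping E-step point: the per-length signals
        # consensus - eps are held fixed, so the deviations implied by the
        # new consensus are eps + (preclip - consensus).
        delta = preclip - consensus.values
        implied = {
            l: DeviationField(l, deviations[l].values + delta) for l in lengths
        }
        post_e = objective(preclip, implied, profiles, blurs)
        trace.append({"iteration": it, "pre_m": pre_m, "post_m": post_m, "post_e": post_e})
        objective_trace.append(post_m)
        consensus = updated
        if it > 0:
            prev = objective_trace[-2]
            if prev > 0 and abs(post_m - prev) / prev < tol:
                converged = True
                break
    if not converged:
        logger.warning("%s: deblur did not converge in %d rounds", ps.transcript_id, max_iter)

    per_length: dict[int, tuple[np.ndarray, int, float]] = {}
    for l in lengths:
        k = shift_for_length(l)
        signal = np.clip(consensus.values - deviations[l].values, 0.0, None)
        per_length[l] = (shift_profile(signal, -k), k, alphas[l])
    return DeblurResult(
        transcript_id=ps.transcript_id,
        consensus=consensus,
        per_length=per_length,
        deviations=deviations,
        objective_trace=objective_trace,
        converged=converged,
        trace=trace,
    )
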