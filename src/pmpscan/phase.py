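"""Phase recovery and complementary gray-code unwrapping.

From ``N`` phase-shifted fringe images ``I_n = A + B cos(theta + 2 pi n / N)``
the per-pixel wrapped phase is recovered in closed form:

    phi = -atan2( sum_n I_n sin(2 pi n / N),  sum_n I_n cos(2 pi n / N) )

(the negation makes ``phi`` equal the projected phase argument ``theta``
modulo 2 pi).  ``A`` is the frame mean and ``B = (2/N) sqrt(S_sin^2 +
S_cos^2)`` the modulation amplitude.  A quadrant-aware two-argument
arctangent with range (-pi, pi] is used throughout: the three-branch unwrap
rule below switches branches exactly at +-pi/2, which a half-range arctan
could not support.

Unwrapping uses two gray-code order maps: ``k1`` from the period-aligned set
and ``k2`` from the half-period-shifted complementary set.  The absolute
phase is

    Phi = phi + 2 pi k2            if phi <= -pi/2
          phi + 2 pi k1            if -pi/2 < phi < pi/2
          phi + 2 pi k2 - 2 pi     if phi >= pi/2

Because ``k1`` transitions coincide with the phase wrap and ``k2``
transitions sit half a period away, each branch only ever consults the order
map whose stripe boundaries are far from the current pixel's phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import gray_order_lut

__all__ = [
    "WrappedPhaseResult",
    "FringeOrderMaps",
    "AbsolutePhaseMap",
    "wrapped_phase",
    "decode_fringe_orders",
    "unwrap_phase",
    "unwrap_phase_single",
    "modulation_mask",
]


@dataclass
class WrappedPhaseResult:
    """Per-pixel wrapped phase ``phi`` in (-pi, pi], DC level and modulation."""

    phi: np.ndarray
    dc: np.ndarray
    modulation: np.ndarray


@dataclass
class FringeOrderMaps:
    """Integer fringe orders: period-aligned ``k1``, shifted ``k2``.

    ``codeword_u`` keeps the raw gray codewords (k1 set) before the
    codeword->order lookup, mainly for diagnostics.
    """

    k1: np.ndarray
    k2: np.ndarray
    codeword_u: np.ndarray


@dataclass
class AbsolutePhaseMap:
    Phi: np.ndarray
    valid_mask: np.ndarray


def _as_float_frames(frames) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.dtype == np.uint8:
        frames = frames.astype(float) / 255.0
    return frames.astype(float, copy=False)


def wrapped_phase(psp_frames, n_steps: int | None = None) -> WrappedPhaseResult:
    """Closed-form N-step phase retrieval.

    Parameters
    ----------
    psp_frames : (N, H, W) array
        Captured fringe frames, uint8 or floats in [0, 1].
    n_steps : int, optional
        Expected N; checked against ``psp_frames.shape[0]`` when given.
    """
    frames = _as_float_frames(psp_frames)
    N = frames.shape[0]
    if n_steps is not None and n_steps != N:
        raise ValueError(f"expected {n_steps} frames, got {N}")
    if N < 3:
        raise ValueError(f"need at least 3 phase-shift frames, got {N}")
    n = np.arange(N)
    s = np.sin(2 * np.pi * n / N)
    c = np.cos(2 * np.pi * n / N)
    S_sin = np.tensordot(s, frames, axes=(0, 0))
    S_cos = np.tensordot(c, frames, axes=(0, 0))
    phi = -np.arctan2(S_sin, S_cos)
    phi = np.where(phi <= -np.pi, phi + 2 * np.pi, phi)  # range (-pi, pi]
    dc = frames.mean(axis=0)
    modulation = (2.0 / N) * np.hypot(S_sin, S_cos)
    return WrappedPhaseResult(phi=phi, dc=dc, modulation=modulation)


def _decode_set(gray_frames: np.ndarray, dc: np.ndarray):
    """Binarize a gray frame set against the per-pixel DC level and decode."""
    m = gray_frames.shape[0]
    bits = gray_frames > dc[None, :, :]
    code = np.zeros(dc.shape, dtype=np.int64)
    for i in range(m):
        code = (code << 1) | bits[i].astype(np.int64)
    lut = gray_order_lut(m)
    return lut[code], code


def decode_fringe_orders(gray_frames_k1, gray_frames_k2, dc, modulation=None) -> FringeOrderMaps:
    """Decode both complementary gray-code sets into fringe-order maps.

    Frames are binarized against the per-pixel DC level ``A`` recovered from
    the PSP stack, which makes the threshold robust to albedo and shading.
    ``modulation`` is accepted for signature symmetry with downstream masking
    but not needed by the decode itself.
    """
    g1 = _as_float_frames(gray_frames_k1)
    dc = np.asarray(dc, dtype=float)
    if g1.size == 0:
        raise ValueError("k1 gray frame set is empty")
    k1, codeword = _decode_set(g1, dc)
    if gray_frames_k2 is None:
        raise ValueError(
            "complementary (k2) gray frames are required for three-branch "
            "unwrapping; pass include_complementary=True when generating patterns"
        )
    g2 = _as_float_frames(gray_frames_k2)
    if g2.size == 0:
        raise ValueError("k2 gray frame set is empty")
    k2, _ = _decode_set(g2, dc)
    return FringeOrderMaps(k1=k1, k2=k2, codeword_u=codeword)


def unwrap_phase(phi, orders: FringeOrderMaps, jump_tol: float = np.pi) -> AbsolutePhaseMap:
    """Three-branch absolute-phase recovery from complementary orders.

    Pixels whose unwrapped phase differs by more than ``jump_tol`` from a
    majority of their 4-neighbors are flagged in ``valid_mask`` (residual
    order errors on discontinuous surfaces).
    """
    phi = np.asarray(phi, dtype=float)
    k1 = orders.k1
    k2 = orders.k2
    two_pi = 2 * np.pi
    Phi = np.where(
        phi <= -np.pi / 2,
        phi + two_pi * k2,
        np.where(phi < np.pi / 2, phi + two_pi * k1, phi + two_pi * k2 - two_pi),
    )
    valid = ~_jump_outliers(Phi, jump_tol)
    return AbsolutePhaseMap(Phi=Phi, valid_mask=valid)


def unwrap_phase_single(phi, k) -> AbsolutePhaseMap:
    """Single-code fallback ``Phi = phi + 2 pi k`` (no complementary set).

    Order errors near stripe boundaries are not corrected; prefer
    :func:`unwrap_phase`.
    """
    phi = np.asarray(phi, dtype=float)
    Phi = phi + 2 * np.pi * np.asarray(k)
    return AbsolutePhaseMap(Phi=Phi, valid_mask=np.ones_like(phi, dtype=bool))


def _jump_outliers(Phi: np.ndarray, tol: float) -> np.ndarray:
    """Pixels disagreeing (> tol) with at least half of their 4-neighbors."""
    bad = np.zeros(Phi.shape, dtype=np.int16)
    cnt = np.zeros(Phi.shape, dtype=np.int16)
    for axis in (0, 1):
        d = np.abs(np.diff(Phi, axis=axis)) > tol
        sl_lo = [slice(None)] * 2
        sl_hi = [slice(None)] * 2
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        bad[tuple(sl_lo)] += d
        bad[tuple(sl_hi)] += d
        cnt[tuple(sl_lo)] += 1
        cnt[tuple(sl_hi)] += 1
    return bad * 2 >= cnt + 1


def modulation_mask(result: WrappedPhaseResult, b_min: float = 0.05,
                    dc_max: float = np.inf) -> np.ndarray:
    """Reliability mask: keep pixels with enough fringe modulation and no
    saturation.

    ``b_min`` rejects shadowed/background pixels (modulation ~ 0) and
    ``dc_max`` rejects saturated ones (clipped sinusoids bias the phase and
    feed halo artifacts).
    """
    if b_min < 0 or dc_max < 0:
        raise ValueError("thresholds must be nonnegative")
    return (result.modulation >= b_min) & (result.dc < dc_max)
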