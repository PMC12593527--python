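"""Projector pattern generation: N-step phase-shift fringes and gray codes.

A scan projects ``N`` sinusoidal fringe images, each shifted by ``2*pi/N``,
plus two binary gray-code sets that label fringe orders:

* the ``k1`` set: ``m`` frames whose stripe bands are period-aligned with the
  fringe (band boundaries fall where the wrapped phase wraps), and
* the complementary ``k2`` set: ``m + 1`` frames whose bands are offset by
  half a fringe period, so their transitions fall where the wrapped phase is
  far from its discontinuity.

The fringe of frame ``n`` at projector column ``u`` is

    I_n(u) = A + B * cos(2*pi*n_periods*u/width + phase_offset + 2*pi*n/N)

with ``phase_offset = -pi`` by default, which centers each fringe peak on a
``k1`` gray band.  This alignment is what makes the three-branch unwrap rule
(see :mod:`pmpscan.phase`) exact with only ``m`` period-aligned code frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PSPSpec",
    "GrayCodeSpec",
    "PatternStack",
    "make_psp_patterns",
    "make_gray_code_patterns",
    "make_scan_patterns",
    "gray_encode",
    "gray_decode",
    "gray_encode_int",
    "gray_decode_int",
]


class PatternConfigError(ValueError):
    """Invalid pattern specification."""


@dataclass(frozen=True)
class PSPSpec:
    """Phase-shift fringe parameters.

    ``mean_level`` (A) and ``amplitude`` (B) are unitless in [0, 1]; the
    generated intensities must not clip, i.e. ``A - B >= 0`` and
    ``A + B <= 1``.  ``axis`` selects the fringe direction: ``"u"`` for
    vertical stripes (phase varies with column) or ``"v"`` for horizontal.
    """

    width_px: int
    height_px: int
    n_steps: int = 12
    n_periods: int = 16
    mean_level: float = 0.5
    amplitude: float = 0.5
    phase_offset: float = -np.pi
    axis: str = "u"

    def __post_init__(self):
        if self.n_steps < 3:
            raise PatternConfigError(
                f"n_steps must be >= 3 (got {self.n_steps}); "
                "phase recovery needs at least three shifted frames"
            )
        if self.n_periods < 1:
            raise PatternConfigError("n_periods must be >= 1")
        if self.mean_level - self.amplitude < -1e-12:
            raise PatternConfigError(
                f"mean_level - amplitude = {self.mean_level - self.amplitude:g} < 0 "
                "would clip at black"
            )
        if self.mean_level + self.amplitude > 1 + 1e-12:
            raise PatternConfigError(
                f"mean_level + amplitude = {self.mean_level + self.amplitude:g} > 1 "
                "would clip at white"
            )
        if self.axis not in ("u", "v"):
            raise PatternConfigError("axis must be 'u' or 'v'")
        if self.fringe_extent % self.n_periods != 0:
            raise PatternConfigError(
                f"pattern extent {self.fringe_extent} px not divisible by "
                f"n_periods={self.n_periods}; fringe periods and gray-code "
                "bands must align exactly"
            )

    @property
    def fringe_extent(self) -> int:
        """Pixel count along the fringe axis."""
        return self.width_px if self.axis == "u" else self.height_px

    @property
    def pixels_per_period(self) -> int:
        return self.fringe_extent // self.n_periods


@dataclass(frozen=True)
class GrayCodeSpec:
    """Gray-code set parameters; normally derived from a :class:`PSPSpec`."""

    width_px: int
    height_px: int
    n_bits: int
    pixels_per_period: float
    include_complementary: bool = True
    axis: str = "u"

    @classmethod
    def for_psp(cls, psp: PSPSpec, include_complementary: bool = True) -> "GrayCodeSpec":
        m = max(1, int(np.ceil(np.log2(psp.n_periods))))
        return cls(
            width_px=psp.width_px,
            height_px=psp.height_px,
            n_bits=m,
            pixels_per_period=psp.pixels_per_period,
            include_complementary=include_complementary,
            axis=psp.axis,
        )

    def __post_init__(self):
        extent = self.width_px if self.axis == "u" else self.height_px
        n_periods = extent / self.pixels_per_period
        if 2 ** self.n_bits < n_periods - 1e-9:
            raise PatternConfigError(
                f"{self.n_bits} gray bits label only {2 ** self.n_bits} bands "
                f"but the pattern has {n_periods:g} fringe periods"
            )


@dataclass
class PatternStack:
    """Ordered projector frames with per-frame kind tags.

    ``kinds[i]`` is one of ``"psp"``, ``"gray_k1"``, ``"gray_k2"``; PSP frames
    are floats in [0, 1], gray frames are binary {0, 1}.
    """

    frames: list
    kinds: list
    psp_spec: PSPSpec | None = None
    gray_spec: GrayCodeSpec | None = None

    def __len__(self):
        return len(self.frames)

    def __add__(self, other: "PatternStack") -> "PatternStack":
        return PatternStack(
            frames=self.frames + other.frames,
            kinds=self.kinds + other.kinds,
            psp_spec=self.psp_spec or other.psp_spec,
            gray_spec=self.gray_spec or other.gray_spec,
        )

    def select(self, kind: str) -> np.ndarray:
        """Frames of one kind as an (n, H, W) array."""
        sel = [f for f, k in zip(self.frames, self.kinds) if k == kind]
        if not sel:
            return np.empty((0, 0, 0))
        return np.stack(sel)

    @property
    def psp_frames(self) -> np.ndarray:
        return self.select("psp")

    @property
    def gray_k1_frames(self) -> np.ndarray:
        return self.select("gray_k1")

    @property
    def gray_k2_frames(self) -> np.ndarray:
        return self.select("gray_k2")

    # -- disk round trip ------------------------------------------------
    _PREFIX = {"psp": "psp", "gray_k1": "gray1", "gray_k2": "gray2"}

    def save(self, directory) -> None:
        """Write 8-bit PNG frames plus a JSON spec sidecar."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        counters: dict[str, int] = {}
        names = []
        for frame, kind in zip(self.frames, self.kinds):
            idx = counters.get(kind, 0)
            counters[kind] = idx + 1
            name = f"{self._PREFIX[kind]}_{idx:02d}.png"
            iio.imwrite(
                directory / name,
                np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8),
            )
            names.append(name)
        meta = {
            "frames": names,
            "kinds": self.kinds,
            "psp_spec": asdict(self.psp_spec) if self.psp_spec else None,
            "gray_spec": asdict(self.gray_spec) if self.gray_spec else None,
        }
        (directory / "patterns.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PatternStack":
        import imageio.v3 as iio

        directory = Path(directory)
        meta = json.loads((directory / "patterns.json").read_text())
        frames = [
            iio.imread(directory / name).astype(float) / 255.0
            for name in meta["frames"]
        ]
        psp = PSPSpec(**meta["psp_spec"]) if meta["psp_spec"] else None
        gray = GrayCodeSpec(**meta["gray_spec"]) if meta["gray_spec"] else None
        return cls(frames=frames, kinds=list(meta["kinds"]), psp_spec=psp, gray_spec=gray)


# ---------------------------------------------------------------------------
# gray code words
# ---------------------------------------------------------------------------

def gray_encode_int(k):
    """Reflected gray codeword of integer(s) ``k`` as integer(s)."""
    k = np.asarray(k)
    return k ^ (k >> 1)


def gray_decode_int(g):
    """Inverse of :func:`gray_encode_int` via the XOR cascade."""
    g = np.asarray(g).copy()
    shift = 1
    # enough iterations for 64-bit words
    while shift < 64:
        g = g ^ (g >> shift)
        shift *= 2
    return g


def gray_encode(k: int, n_bits: int) -> np.ndarray:
    """Gray codeword of ``k`` as an MSB-first bit vector of length ``n_bits``."""
    if not 0 <= k < 2 ** n_bits:
        raise PatternConfigError(f"k={k} outside [0, 2^{n_bits})")
    g = int(gray_encode_int(k))
    return np.array([(g >> (n_bits - 1 - i)) & 1 for i in range(n_bits)], dtype=np.uint8)


def gray_decode(bits, n_bits: int | None = None) -> int:
    """Integer encoded by an MSB-first gray bit vector."""
    bits = np.asarray(bits).astype(np.int64)
    if bits.ndim != 1:
        raise ValueError("gray_decode expects a 1-D bit vector")
    if n_bits is not None and bits.size != n_bits:
        raise ValueError(f"expected {n_bits} bits, got {bits.size}")
    g = 0
    for b in bits:
        g = (g << 1) | int(b)
    return int(gray_decode_int(np.int64(g)))


def gray_order_lut(n_bits: int) -> np.ndarray:
    """Lookup table mapping a raw gray codeword to its band index.

    ``lut[codeword] = k``; this is the explicit codeword->order relation, kept
    as a table so a nonstandard stripe ordering could be swapped in.
    """
    k = np.arange(2 ** n_bits)
    lut = np.empty(2 ** n_bits, dtype=np.int64)
    lut[gray_encode_int(k)] = k
    return lut


# ---------------------------------------------------------------------------
# pattern synthesis
# ---------------------------------------------------------------------------

def _broadcast_columns(values: np.ndarray, spec_axis: str, width: int, height: int):
    if spec_axis == "u":
        return np.broadcast_to(values[None, :], (height, width)).copy()
    return np.broadcast_to(values[:, None], (height, width)).copy()


def make_psp_patterns(spec: PSPSpec) -> PatternStack:
    """Generate the ``N`` phase-shifted sinusoidal fringe frames."""
    x = np.arange(spec.fringe_extent, dtype=float)
    base = 2 * np.pi * spec.n_periods * x / spec.fringe_extent + spec.phase_offset
    frames = []
    for n in range(spec.n_steps):
        profile = spec.mean_level + spec.amplitude * np.cos(base + 2 * np.pi * n / spec.n_steps)
        frames.append(_broadcast_columns(profile, spec.axis, spec.width_px, spec.height_px))
    return PatternStack(frames=frames, kinds=["psp"] * spec.n_steps, psp_spec=spec)


def fringe_band_index(x, pixels_per_period: float, shifted: bool) -> np.ndarray:
    """Band index at fringe-axis coordinate ``x``.

    Period-aligned (``shifted=False``): ``floor(x / p)``; half-period-shifted
    (``shifted=True``): ``floor(x / p + 1/2)``.  Ties at exact boundaries
    resolve toward the lower codeword (floor semantics).
    """
    x = np.asarray(x, dtype=float)
    p = float(pixels_per_period)
    if shifted:
        return np.floor(x / p + 0.5).astype(np.int64)
    return np.floor(x / p).astype(np.int64)


def make_gray_code_patterns(spec: GrayCodeSpec) -> PatternStack:
    """Generate the gray-code frame sets.

    The ``k1`` set has ``n_bits`` period-aligned frames; when
    ``include_complementary`` is set, a second set of ``n_bits + 1`` frames
    with stripe boundaries offset by half a period is appended (source of the
    ``k2`` orders used by the three-branch unwrap).
    """
    extent = spec.width_px if spec.axis == "u" else spec.height_px
    x = np.arange(extent)
    frames, kinds = [], []

    def emit(band, n_bits, kind):
        code = gray_encode_int(band.astype(np.int64))
        for i in range(n_bits):
            bits = ((code >> (n_bits - 1 - i)) & 1).astype(float)
            frames.append(_broadcast_columns(bits, spec.axis, spec.width_px, spec.height_px))
            kinds.append(kind)

    emit(fringe_band_index(x, spec.pixels_per_period, shifted=False), spec.n_bits, "gray_k1")
    if spec.include_complementary:
        emit(fringe_band_index(x, spec.pixels_per_period, shifted=True), spec.n_bits + 1, "gray_k2")
    return PatternStack(frames=frames, kinds=kinds, gray_spec=spec)


def make_scan_patterns(psp: PSPSpec, include_complementary: bool = True) -> PatternStack:
    """Full projection sequence for one scan: PSP frames then gray codes."""
    gray = GrayCodeSpec.for_psp(psp, include_complementary=include_complementary)
    stack = make_psp_patterns(psp) + make_gray_code_patterns(gray)
    return stack
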