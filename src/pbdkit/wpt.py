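"""2D wavelet packet and wavelet pyramid decompositions.

A separable quadrature-mirror filter bank splits every block into four
children — row/column low/high combinations, downsampled by two per axis.
The packet transform re-splits *all* blocks recursively, producing the full
tree with ``4**level`` terminal subbands; the classical Mallat pyramid
re-splits only the approximation block and yields ``3*level + 1`` blocks.

Subband channels follow natural (Paley) order: within every parent the
children are LL, LH, HL, HH, recursively.  Channel ``m`` at depth ``d``
therefore reads as a base-4 number whose digits (most significant first)
are the split choices from the root.  The ordering is fixed so that
feature vectors built from the subbands are comparable across runs.

Filtering is delegated to PyWavelets; this module owns the tree indexing,
padding of non-dyadic inputs and the validated transform configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import ConfigurationError, SizeError, ValidationError

# child index -> PyWavelets 2D node key (LL, LH, HL, HH)
_CHILD_KEYS = ("a", "h", "v", "d")

#: user-facing boundary mode -> PyWavelets signal extension mode
_BOUNDARY_MODES = {"periodic": "periodization", "symmetric": "symmetric"}

#: boundary mode -> numpy.pad mode used to grow non-dyadic inputs
_PAD_MODES = {"periodic": "wrap", "symmetric": "symmetric"}


@dataclass(frozen=True)
class WaveletSpec:
    """A validated wavelet filter pair plus boundary handling.

    Parameters
    ----------
    name:
        PyWavelets wavelet family identifier (``"haar"``, ``"db4"``, ...).
    boundary:
        Signal extension mode, ``"periodic"`` (default; exact energy
        conservation and exact coefficient counts on dyadic images) or
        ``"symmetric"``.
    """

    name: str = "haar"
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.boundary not in _BOUNDARY_MODES:
            raise ConfigurationError(
                f"unknown boundary mode {self.boundary!r}; "
                f"expected one of {sorted(_BOUNDARY_MODES)}"
            )
        try:
            w = pywt.Wavelet(self.name)
        except ValueError as exc:
            raise ConfigurationError(f"unknown wavelet {self.name!r}") from exc
        lo, hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
        if len(lo) != len(hi) or len(lo) < 2:
            raise ConfigurationError(
                f"wavelet {self.name!r} filter pair must have equal length >= 2"
            )
        if w.orthogonal:
            for taps in (lo, hi):
                if abs(np.sum(taps**2) - 1.0) > 1e-10:
                    raise ConfigurationError(
                        f"wavelet {self.name!r} declared orthogonal but its "
                        "filters are not orthonormal"
                    )

    @property
    def lowpass(self) -> np.ndarray:
        """Decomposition low-pass filter taps."""
        return np.asarray(pywt.Wavelet(self.name).dec_lo)

    @property
    def highpass(self) -> np.ndarray:
        """Decomposition high-pass filter taps."""
        return np.asarray(pywt.Wavelet(self.name).dec_hi)

    @property
    def pywt_mode(self) -> str:
        return _BOUNDARY_MODES[self.boundary]


@dataclass
class SubbandTree:
    """Full wavelet packet tree of one 2D image.

    ``subbands`` maps ``(depth, channel)`` to a coefficient block for every
    depth ``1..level`` and channel ``0..4**depth - 1``.  ``source_shape`` is
    the original image size; ``padded_shape`` is the (possibly larger)
    dyadic-multiple size actually transformed.
    """

    level: int
    subbands: dict[tuple[int, int], np.ndarray]
    source_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)

    def leaves(self) -> list[np.ndarray]:
        """Terminal subbands in channel order (length ``4**level``)."""
        return [self.subbands[(self.level, m)] for m in range(4**self.level)]

    def energy(self) -> float:
        """Total squared-coefficient energy of the terminal subbands."""
        return float(sum((b**2).sum() for b in self.leaves()))


def _channel_path(m: int, depth: int) -> str:
    """Base-4 digits of channel ``m`` rendered as a PyWavelets node path."""
    digits = []
    for _ in range(depth):
        digits.append(m % 4)
        m //= 4
    return "".join(_CHILD_KEYS[c] for c in reversed(digits))


def _prepare(image: np.ndarray, wavelet: WaveletSpec, level: int) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2D image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    if level < 1:
        raise ValidationError(f"level must be >= 1, got {level}")
    block = 2**level
    if min(image.shape) < block:
        raise SizeError(
            f"image of shape {image.shape} too small for a level-{level} "
            f"decomposition (needs at least {block} rows and columns)"
        )
    pad_r = (-image.shape[0]) % block
    pad_c = (-image.shape[1]) % block
    if pad_r or pad_c:
        image = np.pad(image, ((0, pad_r), (0, pad_c)),
                       mode=_PAD_MODES[wavelet.boundary])
    return image


def wpt_decompose(
    image: np.ndarray, wavelet: WaveletSpec | str = "haar", level: int = 2
) -> SubbandTree:
    """Full 2D wavelet packet decomposition to the given depth.

    Every block at every depth is split into four half-size children
    (LL, LH, HL, HH), so depth ``d`` holds exactly ``4**d`` subbands.
    Non-dyadic inputs are padded (with the wavelet's boundary mode) to the
    next multiple of ``2**level``; the original shape is recorded on the
    returned tree so reconstruction can crop back.
    """
    if isinstance(wavelet, str):
        wavelet = WaveletSpec(wavelet)
    source_shape = tuple(np.asarray(image).shape[:2])
    padded = _prepare(image, wavelet, level)
    wp = pywt.WaveletPacket2D(padded, wavelet.name, mode=wavelet.pywt_mode,
                              maxlevel=level)
    subbands: dict[tuple[int, int], np.ndarray] = {}
    for d in range(1, level + 1):
        for m in range(4**d):
            subbands[(d, m)] = np.asarray(wp[_channel_path(m, d)].data, dtype=float)
    return SubbandTree(
        level=level,
        subbands=subbands,
        source_shape=source_shape,  # type: ignore[arg-type]
        padded_shape=padded.shape,
        wavelet=wavelet,
    )


def wpt_reconstruct(tree: SubbandTree, wavelet: WaveletSpec | str | None = None) -> np.ndarray:
    """Invert :func:`wpt_decompose` from the terminal subbands.

    The wavelet, when given, must match the one recorded on the tree; the
    output is cropped to the tree's ``source_shape``.
    """
    if wavelet is None:
        wavelet = tree.wavelet
    elif isinstance(wavelet, str):
        wavelet = WaveletSpec(wavelet)
    if wavelet.name != tree.wavelet.name:
        raise ConfigurationError(
            f"tree was built with wavelet {tree.wavelet.name!r}, "
            f"reconstruction requested with {wavelet.name!r}"
        )
    wp = pywt.WaveletPacket2D(data=None, wavelet=wavelet.name,
                              mode=wavelet.pywt_mode)
    for m in range(4**tree.level):
        wp[_channel_path(m, tree.level)] = tree.subbands[(tree.level, m)]
    rec = wp.reconstruct(update=False)
    return np.asarray(rec)[: tree.source_shape[0], : tree.source_shape[1]]


def dwt_decompose(
    image: np.ndarray, wavelet: WaveletSpec | str = "haar", level: int = 2
) -> list[np.ndarray]:
    """Mallat pyramid decomposition: ``3*level + 1`` blocks.

    Only the approximation is re-split at each depth.  Blocks are returned
    coarse to fine: the final approximation first, then (LH, HL, HH) per
    level from coarsest to finest.  At ``level == 1`` the four blocks equal
    the level-1 packet subbands.
    """
    if isinstance(wavelet, str):
        wavelet = WaveletSpec(wavelet)
    padded = _prepare(image, wavelet, level)
    coeffs = pywt.wavedec2(padded, wavelet.name, mode=wavelet.pywt_mode,
                           level=level)
    blocks: list[np.ndarray] = [np.asarray(coeffs[0], dtype=float)]
    for detail in coeffs[1:]:
        blocks.extend(np.asarray(b, dtype=float) for b in detail)
    return blocks


def export_subbands(tree: SubbandTree, out_dir, depth: int | None = None) -> list:
    """Write each subband at ``depth`` (default: terminal) as a PNG.

    Intended for visual inspection of how the packet transform distributes
    image structure across channels.  Each block is min-max scaled to 8-bit
    independently.  Returns the written paths.
    """
    import pathlib

    import imageio.v3 as iio

    depth = tree.level if depth is None else depth
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in range(4**depth):
        block = tree.subbands[(depth, m)]
        lo, hi = block.min(), block.max()
        scaled = np.zeros_like(block) if hi == lo else (block - lo) / (hi - lo)
        path = out / f"subband_d{depth}_m{m:02d}.png"
        iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
        paths.append(path)
    return paths
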