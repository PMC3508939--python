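"""Synthetic validation data: windowed waveforms, Gaussian-blob images,
transfer-function mixing and symmetric noise injection.

The default ("blobs") configuration builds five temporal sources of 256
samples (1 s at 256 Hz), five 16x16-pixel spatial sources made of 2-4
rotated anisotropic Gaussians each, and links them: spatial mixing columns are
the convolved-and-decimated temporal sources, temporal mixing columns are the
sixteen 4x4-block mean intensities of the spatial images. Surrogate 1/f-noise
or user-audio generators emulate naturalistic-signal studies without any
download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transfer import TransferConfig, apply_transfer, standardize

__all__ = [
    "GroundTruth",
    "BlobSpec",
    "make_blobs_temporal",
    "make_blobs_spatial",
    "mix",
    "block_means",
    "add_noise",
    "make_blobs_dataset",
    "make_surrogate_naturalistic",
    "DEFAULT_INV_SNR_GRID",
]

N_TRUE_SOURCES = 5
BLOBS_N_SAMPLES = 256  # 1 s at 256 Hz
BLOBS_IMAGE_SIZE = 16
BLOBS_N_BLOBS = (2, 4)
SPEECH_IMAGE_SIZE = 128
SPEECH_N_BLOBS = (4, 15)
#: noise-variance grid spanning 1e-2 .. 1e2 (seven inverse-SNR levels)
DEFAULT_INV_SNR_GRID = (0.01, 0.1, 0.5, 1.0, 2.0, 10.0, 100.0)
#: blob sharpness range: quadratic-form diagonal entries in unit-square
#: coordinates; chosen so blob widths span roughly 10-50% of the image
DEFAULT_HESSIAN_RANGE = (10.0, 300.0)


@dataclass(frozen=True)
class BlobSpec:
    """Parameters of one randomly placed rotated Gaussian blob."""

    center: tuple[float, float]
    hessian_diag: tuple[float, float]
    theta: float

    def __post_init__(self) -> None:
        if min(self.hessian_diag) <= 0:
            raise ValueError("Hessian diagonal entries must be positive")


@dataclass
class GroundTruth:
    """The generating sources, mixing matrices and pairing of one dataset."""

    temporal_sources: np.ndarray  # 5 x N_TT
    spatial_sources: np.ndarray  # 5 x N_SS
    temporal_mixing: np.ndarray  # N_TS x 5
    spatial_mixing: np.ndarray  # N_ST x 5
    pairing: np.ndarray  # pairing[j] = spatial index of temporal source j
    transfer: TransferConfig
    image_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        return self.temporal_sources.shape[0]


def _gaussian_pulse(n: int, center: float, width: float) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((t - center * n) / (width * n)) ** 2)


def _blackman(m: int) -> np.ndarray:
    from scipy.signal import windows

    return windows.blackman(m)


def make_blobs_temporal(seed: int, n_samples: int = BLOBS_N_SAMPLES) -> np.ndarray:
    """Five standardized simple waveforms with limited temporal support/overlap.

    The exact shapes are a repository fixture: a windowed sinusoid burst, two
    Blackman windows at distinct offsets, a Gaussian pulse and a double
    Gaussian pulse, jittered slightly by ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = int(n_samples)
    jitter = rng.integers(-n // 64, n // 64 + 1, size=N_TRUE_SOURCES)
    out = np.zeros((N_TRUE_SOURCES, n))

    # supports are staggered across the record so overlap stays small
    # 1. sinusoid burst, early
    m = int(0.28 * n)
    start = max(0, int(0.02 * n) + jitter[0])
    t = np.arange(m)
    out[0, start : start + m] = np.sin(2 * np.pi * 5 * t / m) * _blackman(m)

    # 2. Blackman window, early-middle
    m = int(0.22 * n)
    start = min(n - m, max(0, int(0.26 * n) + jitter[1]))
    out[1, start : start + m] = _blackman(m)

    # 3. Gaussian pulse, middle
    out[2] = _gaussian_pulse(n, 0.55 + jitter[2] / n, 0.03)

    # 4. Blackman window, late-middle
    m = int(0.20 * n)
    start = min(n - m, max(0, int(0.62 * n) + jitter[3]))
    out[3, start : start + m] = _blackman(m)

    # 5. double Gaussian pulse, late
    c = 0.9 + jitter[4] / n
    out[4] = _gaussian_pulse(n, c, 0.018) + 0.8 * _gaussian_pulse(n, c - 0.08, 0.018)

    return standardize(out, axis=1)


def _render_blob(size: int, spec: BlobSpec) -> np.ndarray:
    """Evaluate exp(-(r-r0)^T R(theta)^T H R(theta) (r-r0)) on the pixel grid."""
    coords = (np.arange(size) + 0.5) / size  # pixel centers in the unit square
    xx, yy = np.meshgrid(coords, coords)
    dx = xx - spec.center[0]
    dy = yy - spec.center[1]
    ct, st = np.cos(spec.theta), np.sin(spec.theta)
    # rotated offsets: u = R @ (r - r0)
    u = ct * dx - st * dy
    v = st * dx + ct * dy
    h1, h2 = spec.hessian_diag
    return np.exp(-(h1 * u**2 + h2 * v**2))


def make_blobs_spatial(
    seed: int,
    image_size: int = BLOBS_IMAGE_SIZE,
    n_blobs_range: tuple[int, int] = BLOBS_N_BLOBS,
    hessian_range: tuple[float, float] = DEFAULT_HESSIAN_RANGE,
    n_sources: int = N_TRUE_SOURCES,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Standardized images of randomly placed rotated Gaussian blobs.

    Each image is the sum of k ~ Uniform{n_blobs_range} non-normalized
    Gaussians with random centers in the unit square, random diagonal
    quadratic forms from ``hessian_range`` and random rotations. Images are
    flattened row-major; returns (n_sources x image_size**2 matrix, shape).
    """
    if image_size < 4:
        raise ValueError("image_size must be >= 4")
    lo, hi = n_blobs_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid blob-count range {n_blobs_range}")
    rng = np.random.default_rng(seed)
    images = np.zeros((n_sources, image_size * image_size))
    for i in range(n_sources):
        k = int(rng.integers(lo, hi + 1))
        img = np.zeros((image_size, image_size))
        for _ in range(k):
            spec = BlobSpec(
                center=tuple(rng.uniform(0, 1, size=2)),
                hessian_diag=tuple(rng.uniform(*hessian_range, size=2)),
                theta=float(rng.uniform(0, np.pi)),
            )
            img += _render_blob(image_size, spec)
        images[i] = img.ravel()
    return standardize(images, axis=1), (image_size, image_size)


def block_means(image: np.ndarray, shape: tuple[int, int], grid: tuple[int, int] = (4, 4)) -> np.ndarray:
    """Mean intensity of each grid block, row-major block order."""
    H, W = shape
    gh, gw = grid
    if H % gh != 0 or W % gw != 0:
        raise ValueError(f"block grid {grid} does not tile image shape {shape}")
    img = np.asarray(image, dtype=float).reshape(H, W)
    bh, bw = H // gh, W // gw
    return img.reshape(gh, bh, gw, bw).mean(axis=(1, 3)).ravel()


def mix(
    temporal_sources: np.ndarray,
    spatial_sources: np.ndarray,
    image_shape: tuple[int, int],
    transfer: TransferConfig,
    block_grid: tuple[int, int] = (4, 4),
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Link and mix paired sources into the two data matrices.

    Spatial mixing column j is the transfer-transformed temporal source j
    (convolved, decimated by q, standardized): X_S = A_S @ S_S. Temporal
    mixing column j holds the block-mean intensities of spatial source j over
    ``block_grid``: X_T = A_T @ S_T. Source j of one modality is paired with
    source j of the other.
    """
    S_T = np.asarray(temporal_sources, dtype=float)
    S_S = np.asarray(spatial_sources, dtype=float)
    if S_T.shape[0] != S_S.shape[0]:
        raise ValueError("temporal and spatial source counts differ")
    n_tt = S_T.shape[1]
    if n_tt % transfer.q != 0:
        raise ValueError(f"decimation q={transfer.q} does not divide N_TT={n_tt}")
    A_S = np.column_stack([apply_transfer(row, transfer) for row in S_T])
    A_T = np.column_stack([block_means(img, image_shape, block_grid) for img in S_S])
    X_S = A_S @ S_S
    X_T = A_T @ S_T
    truth = GroundTruth(
        temporal_sources=S_T,
        spatial_sources=S_S,
        temporal_mixing=A_T,
        spatial_mixing=A_S,
        pairing=np.arange(S_T.shape[0]),
        transfer=transfer,
        image_shape=tuple(image_shape),
        meta={"block_grid": tuple(block_grid)},
    )
    return X_T, X_S, truth


def add_noise(
    X_T: np.ndarray, X_S: np.ndarray, sigma2: float, seed: int
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Symmetric Gaussian noise injection.

    Each matrix is first rescaled to unit total variance, then i.i.d.
    N(0, sigma2) noise is added to both. Returns (noisy X_T, noisy X_S, snr)
    with snr = 1/sigma2 (None when sigma2 == 0).
    """
    if sigma2 < 0:
        raise ValueError("noise variance must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for X in (X_T, X_S):
        X = np.asarray(X, dtype=float)
        v = X.var()
        if v == 0:
            warnings.warn("matrix has zero variance; skipping unit-variance scaling", RuntimeWarning)
            Xn = X.copy()
        else:
            Xn = X / np.sqrt(v)
        if sigma2 > 0:
            Xn = Xn + rng.normal(0.0, np.sqrt(sigma2), size=Xn.shape)
        out.append(Xn)
    snr = None if sigma2 == 0 else 1.0 / sigma2
    return out[0], out[1], snr


def make_blobs_dataset(
    seed: int,
    transfer: TransferConfig | None = None,
    sigma2: float = 0.0,
    image_size: int = BLOBS_IMAGE_SIZE,
    n_samples: int = BLOBS_N_SAMPLES,
) -> tuple[np.ndarray, np.ndarray, GroundTruth, float | None]:
    """Convenience wrapper: generate, mix and (optionally) corrupt BLOBS data."""
    if transfer is None:
        transfer = TransferConfig()
    rng = np.random.default_rng(seed)
    seed_t, seed_s, seed_n = (int(s) for s in rng.integers(0, 2**31, size=3))
    S_T = make_blobs_temporal(seed_t, n_samples=n_samples)
    S_S, shape = make_blobs_spatial(seed_s, image_size=image_size)
    X_T, X_S, truth = mix(S_T, S_S, shape, transfer)
    X_T, X_S, snr = add_noise(X_T, X_S, sigma2, seed_n)
    truth.meta.update({"sigma2": sigma2, "snr": snr, "seed": seed})
    return X_T, X_S, truth, snr


def _colored_noise(rng: np.random.Generator, n: int, slope: float = -1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ f^slope."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec *= f ** (slope / 2.0)
    spec[0] = 0.0
    return np.fft.irfft(spec, n=n)


def make_surrogate_naturalistic(
    seed: int,
    n_samples: int = SPEECH_IMAGE_SIZE**2,
    kind: str = "colored-noise",
    source_path: str | None = None,
    n_sources: int = N_TRUE_SOURCES,
) -> np.ndarray:
    """Standardized 1-D surrogates for naturalistic recordings.

    ``colored-noise``: independent 1/f-spectrum Gaussian signals.
    ``audio-file``: random contiguous windows from a WAV file (averaged to
    mono), one window per source.
    """
    rng = np.random.default_rng(seed)
    if kind == "colored-noise":
        out = np.vstack([_colored_noise(rng, n_samples) for _ in range(n_sources)])
    elif kind == "audio-file":
        if source_path is None:
            raise ValueError("audio-file surrogates require source_path")
        from scipy.io import wavfile

        _, wav = wavfile.read(source_path)
        wav = np.asarray(wav, dtype=float)
        if wav.ndim == 2:
            wav = wav.mean(axis=1)
        if wav.size < n_samples:
            raise ValueError(
                f"audio file has {wav.size} samples, need at least {n_samples}"
            )
        starts = rng.integers(0, wav.size - n_samples + 1, size=n_sources)
        out = np.vstack([wav[s : s + n_samples] for s in starts])
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")
    return standardize(out, axis=1)
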