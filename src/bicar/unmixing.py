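"""Repeated stochastic ICA decompositions of one data matrix.

Each data matrix X (mixtures x samples) is decomposed K times under the
linear model X ~ A @ S + offset, with independently seeded runs of symmetric
fixed-point ICA (FastICA, log-cosh contrast). Source rows are standardized to
zero mean / unit variance so all scale lives in the mixing columns; later
pairing steps rely on Pearson correlations, which this convention keeps
meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "DataMatrix",
    "Decomposition",
    "run_realizations",
    "reconstruction_error",
    "fastica_backend",
]

Modality = Literal["temporal", "spatial"]

#: backend contract: (data, n_components, seed) -> (mixing, sources, converged)
IcaBackend = Callable[[np.ndarray, int, int], tuple[np.ndarray, np.ndarray, bool]]

ICA_TOL = 1e-6
ICA_MAX_ITER = 500
ICA_MAX_RETRIES = 3


@dataclass
class DataMatrix:
    """A numeric data matrix with axis roles (mixtures x samples).

    Temporal data: rows are sensors, columns are time samples (fast grid).
    Spatial data: rows are time frames (slow grid), columns are pixels.
    """

    values: np.ndarray
    modality: Modality
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("data matrix contains non-finite entries")
        if self.modality not in ("temporal", "spatial"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n_mix, n_samp = self.values.shape
        if self.modality == "temporal" and n_samp <= n_mix:
            warnings.warn(
                f"temporal matrix has {n_samp} samples <= {n_mix} sensors; "
                "expected many more time samples than sensors",
                RuntimeWarning,
            )
        if self.modality == "spatial" and n_samp <= n_mix:
            warnings.warn(
                f"spatial matrix has {n_samp} pixels <= {n_mix} frames; "
                "expected many more pixels than frames",
                RuntimeWarning,
            )

    @property
    def n_mixtures(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Decomposition:
    """One ICA realization: mixing (mixtures x N_C), sources (N_C x samples).

    ``offset`` is the per-mixture mean removed before ICA; the model is
    data ~ mixing @ sources + offset[:, None]. The un-modeled residual is the
    noise term of the linear source-separation model.
    """

    mixing: np.ndarray
    sources: np.ndarray
    realization_index: int
    seed: int
    modality: Modality
    offset: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.sources = np.asarray(self.sources, dtype=float)
        if self.mixing.shape[1] != self.sources.shape[0]:
            raise ValueError(
                f"mixing has {self.mixing.shape[1]} columns but sources has "
                f"{self.sources.shape[0]} rows"
            )
        if self.offset is None:
            self.offset = np.zeros(self.mixing.shape[0])
        self.offset = np.asarray(self.offset, dtype=float)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources + self.offset[:, None]


def fastica_backend(
    data: np.ndarray, n_components: int, seed: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Symmetric fixed-point ICA with log-cosh contrast on row-centered data.

    ``data`` is mixtures x samples; returns (mixing, sources, converged) with
    sources standardized row-wise and mixing carrying all scale.
    """
    rng = np.random.default_rng(seed)
    # random orthogonal initialization from this realization's stream
    w0 = np.linalg.qr(rng.standard_normal((n_components, n_components)))[0]
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=ICA_MAX_ITER,
        tol=ICA_TOL,
        w_init=w0,
        random_state=int(seed) % (2**32),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            # sklearn's sample axis is rows: feed samples x mixtures
            s = ica.fit_transform(data.T)  # samples x N_C
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_components,
                    algorithm="parallel",
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=ICA_MAX_ITER,
                    tol=ICA_TOL,
                    w_init=w0,
                    random_state=int(seed) % (2**32),
                )
                s = ica.fit_transform(data.T)
    sources = s.T  # N_C x samples
    mixing = ica.mixing_.copy()  # mixtures x N_C
    # re-standardize exactly (sklearn's unit-variance whitening uses ddof=0
    # but finite-precision drift accumulates through the rotation)
    sd = sources.std(axis=1, keepdims=True)
    mu = sources.mean(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources = (sources - mu) / sd
    mixing = mixing * sd.T
    return mixing, sources, converged


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent per-realization seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1, dtype=np.uint64)[0] % (2**31)) for child in ss.spawn(n)]


def run_realizations(
    data: DataMatrix,
    n_components: int,
    n_realizations: int,
    master_seed: int,
    backend: IcaBackend = fastica_backend,
    strict_convergence: bool = False,
) -> list[Decomposition]:
    """Run ``n_realizations`` independently seeded ICA decompositions.

    Non-convergent runs are retried with fresh seeds up to ICA_MAX_RETRIES;
    after that the run is kept with ``converged=False`` (or raised if
    ``strict_convergence``). The master seed deterministically spawns all
    per-realization seeds, so identical inputs give identical outputs.
    """
    if n_realizations < 2:
        raise ValueError(
            f"n_realizations must be >= 2 (cross-realization correlations need at "
            f"least two runs), got {n_realizations}"
        )
    X = data.values
    max_nc = min(X.shape)
    if n_components > max_nc:
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)={max_nc}"
        )
    offset = X.mean(axis=1)
    Xc = X - offset[:, None]
    rank = np.linalg.matrix_rank(Xc)
    if rank < n_components:
        raise ValueError(
            f"data supports at most {rank} components (centered rank) but "
            f"{n_components} were requested"
        )
    # one seed per realization plus a pool of retry seeds
    seeds = spawn_seeds(master_seed, n_realizations * (ICA_MAX_RETRIES + 1))
    primary, retry_pool = seeds[:n_realizations], seeds[n_realizations:]
    decs: list[Decomposition] = []
    for k in range(n_realizations):
        seed = primary[k]
        mixing, sources, converged = backend(Xc, n_components, seed)
        tries = 0
        while not converged and tries < ICA_MAX_RETRIES:
            seed = retry_pool[k * ICA_MAX_RETRIES + tries]
            mixing, sources, converged = backend(Xc, n_components, seed)
            tries += 1
        if not converged:
            if strict_convergence:
                raise RuntimeError(
                    f"realization {k}: ICA failed to converge after "
                    f"{ICA_MAX_RETRIES} seed retries"
                )
            warnings.warn(
                f"realization {k}: ICA not converged after {ICA_MAX_RETRIES} "
                "retries; keeping last run",
                RuntimeWarning,
            )
        decs.append(
            Decomposition(
                mixing=mixing,
                sources=sources,
                realization_index=k,
                seed=seed,
                modality=data.modality,
                offset=offset,
                converged=converged,
            )
        )
    return decs


def reconstruction_error(dec: Decomposition, data: DataMatrix) -> float:
    """Relative Frobenius residual ||X - (A S + offset)|| / ||X||."""
    X = data.values
    if dec.mixing.shape[0] != X.shape[0] or dec.sources.shape[1] != X.shape[1]:
        raise ValueError(
            f"decomposition shape ({dec.mixing.shape[0]} x {dec.sources.shape[1]}) "
            f"does not match data shape {X.shape}"
        )
    denom = np.linalg.norm(X)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(X - dec.reconstruct()) / denom)
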