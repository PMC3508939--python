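"""HDF5 / CSV / YAML persistence for data matrices, results and run configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fusion import BICARResult
from .synth import GroundTruth
from .transfer import TransferConfig
from .unmixing import DataMatrix, Decomposition

__all__ = [
    "RunConfig",
    "load_data_matrices",
    "save_dataset",
    "load_ground_truth",
    "save_result",
    "load_result",
    "save_realizations",
    "load_realizations",
]


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable)."""

    n_components: int
    master_seed: int = 0
    n_realizations: int = 30
    w_T: float = 0.5
    w_S: float = 0.5
    similarity: str = "weighted"
    transfer: TransferConfig = field(default_factory=TransferConfig)
    input_path: str | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_realizations < 2:
            raise ValueError("n_realizations must be >= 2")
        if self.w_T < 0 or self.w_S < 0 or self.w_T + self.w_S <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if self.similarity not in ("weighted", "concatenated"):
            raise ValueError(f"unknown similarity mode {self.similarity!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["transfer"] = self.transfer.to_dict()
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "transfer" in raw:
            raw["transfer"] = TransferConfig.from_dict(raw["transfer"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid run config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_data_matrices(path: str | Path) -> tuple[DataMatrix, DataMatrix]:
    """Read /X_T and /X_S from an HDF5 file (or <stem>_XT.csv / _XS.csv)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            for name in ("X_T", "X_S"):
                if name not in fh:
                    raise KeyError(f"dataset /{name} missing from {path}")
            X_T = fh["X_T"][()]
            X_S = fh["X_S"][()]
    elif path.suffix == ".csv":
        X_T = pd.read_csv(path.with_name(path.stem + "_XT.csv"), header=None).to_numpy()
        X_S = pd.read_csv(path.with_name(path.stem + "_XS.csv"), header=None).to_numpy()
    else:
        raise ValueError(f"unsupported input format {path.suffix!r}")
    return DataMatrix(X_T, "temporal"), DataMatrix(X_S, "spatial")


def save_dataset(
    path: str | Path,
    X_T: np.ndarray,
    X_S: np.ndarray,
    truth: GroundTruth | None = None,
) -> None:
    """Write the two data matrices (and optionally ground truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X_T", data=np.asarray(X_T, dtype=float))
        fh.create_dataset("X_S", data=np.asarray(X_S, dtype=float))
        if truth is not None:
            g = fh.create_group("truth")
            g.create_dataset("S_T", data=truth.temporal_sources)
            g.create_dataset("S_S", data=truth.spatial_sources)
            g.create_dataset("A_T", data=truth.temporal_mixing)
            g.create_dataset("A_S", data=truth.spatial_mixing)
            g.create_dataset("pairing", data=truth.pairing)
            g.attrs["image_shape"] = truth.image_shape
            g.attrs["transfer"] = json.dumps(truth.transfer.to_dict())
            g.attrs["meta"] = json.dumps(truth.meta, default=str)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as fh:
        if "truth" not in fh:
            raise KeyError(f"group /truth missing from {path}")
        g = fh["truth"]
        return GroundTruth(
            temporal_sources=g["S_T"][()],
            spatial_sources=g["S_S"][()],
            temporal_mixing=g["A_T"][()],
            spatial_mixing=g["A_S"][()],
            pairing=g["pairing"][()],
            transfer=TransferConfig.from_dict(json.loads(g.attrs["transfer"])),
            image_shape=tuple(int(x) for x in g.attrs["image_shape"]),
            meta=json.loads(g.attrs["meta"]),
        )


def save_result(path: str | Path, result: BICARResult) -> None:
    """HDF5 result container plus JSON provenance sidecar and CSV spectrum."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("result")
        g.create_dataset("S_T", data=result.temporal_sources)
        g.create_dataset("S_S", data=result.spatial_sources)
        g.create_dataset("A_T", data=result.temporal_mixing)
        g.create_dataset("A_S", data=result.spatial_mixing)
        g.create_dataset("reproducibility", data=result.reproducibility)
    path.with_suffix(".provenance.json").write_text(
        json.dumps(result.provenance, indent=2, default=str)
    )
    pd.DataFrame(
        {
            "component": np.arange(result.n_components),
            "reproducibility": result.reproducibility,
        }
    ).to_csv(path.with_suffix(".spectrum.csv"), index=False)


def load_result(path: str | Path) -> BICARResult:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        g = fh["result"]
        result = BICARResult(
            temporal_sources=g["S_T"][()],
            spatial_sources=g["S_S"][()],
            temporal_mixing=g["A_T"][()],
            spatial_mixing=g["A_S"][()],
            reproducibility=g["reproducibility"][()],
        )
    sidecar = path.with_suffix(".provenance.json")
    if sidecar.exists():
        result.provenance = json.loads(sidecar.read_text())
    return result


def save_realizations(path: str | Path, decs: list[Decomposition], group: str = "realizations") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for d in decs:
            sub = g.create_group(str(d.realization_index))
            sub.create_dataset("A", data=d.mixing)
            sub.create_dataset("S", data=d.sources)
            sub.create_dataset("offset", data=d.offset)
            sub.attrs["seed"] = d.seed
            sub.attrs["modality"] = d.modality
            sub.attrs["converged"] = d.converged


def load_realizations(path: str | Path, group: str = "realizations") -> list[Decomposition]:
    decs = []
    with h5py.File(path, "r") as fh:
        g = fh[group]
        for key in sorted(g, key=int):
            sub = g[key]
            decs.append(
                Decomposition(
                    mixing=sub["A"][()],
                    sources=sub["S"][()],
                    realization_index=int(key),
                    seed=int(sub.attrs["seed"]),
                    modality=str(sub.attrs["modality"]),
                    offset=sub["offset"][()],
                    converged=bool(sub.attrs["converged"]),
                )
            )
    return decs
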