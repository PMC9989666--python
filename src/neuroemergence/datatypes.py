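"""Core in-memory containers shared by every analysis stage.

Two containers cover the whole pipeline: a regional timeseries (regions x
timepoints, with a repetition time) and a structural connectome (symmetric
non-negative weighted adjacency matrix).  Both are thin, validated wrappers
around numpy arrays and both round-trip to plain delimited text with a small
YAML sidecar so that empirical and simulated data flow through identical code
paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml


def _default_labels(n: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(n)]


@dataclass
class RegionalTimeseries:
    """Regional BOLD-like signals.

    Parameters
    ----------
    data:
        Array of shape ``(n_regions, n_timepoints)``.
    tr:
        Repetition time in seconds (the sampling interval of the series).
    labels:
        Region names; generated if omitted.
    """

    data: np.ndarray
    tr: float
    labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be 2-D (regions x timepoints)")
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not self.labels:
            self.labels = _default_labels(self.data.shape[0])
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match number of regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "RegionalTimeseries":
        return replace(self, data=np.asarray(data, dtype=float))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.data, delimiter="\t")
        sidecar = {
            "kind": "regional_timeseries",
            "tr": float(self.tr),
            "labels": list(self.labels),
            **self.meta,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "RegionalTimeseries":
        path = Path(path)
        data = _load_matrix(path)
        side = _load_sidecar(path)
        tr = float(side.pop("tr", 2.0))
        labels = list(side.pop("labels", []))
        side.pop("kind", None)
        return cls(data=data, tr=tr, labels=labels, meta=side)


@dataclass
class StructuralConnectome:
    """Weighted structural network (streamline-count-like adjacency matrix)."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("connectome must be symmetric")
        if (w < 0).any():
            raise ValueError("connectome weights must be non-negative")
        if not self.labels:
            self.labels = _default_labels(w.shape[0])
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def strength(self) -> np.ndarray:
        """Node strength (sum of incident edge weights)."""
        return self.weights.sum(axis=0)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.weights, delimiter="\t")
        sidecar = {
            "kind": "structural_connectome",
            "labels": list(self.labels),
            "normalized": bool(self.normalized),
            **self.meta,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "StructuralConnectome":
        path = Path(path)
        w = _load_matrix(path)
        side = _load_sidecar(path)
        labels = list(side.pop("labels", []))
        normalized = bool(side.pop("normalized", False))
        side.pop("kind", None)
        return cls(weights=w, labels=labels, normalized=normalized, meta=side)


def _load_matrix(path: Path) -> np.ndarray:
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite entries in matrix file {path}")
    return data


def _load_sidecar(path: Path) -> dict:
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if sidecar_path.exists():
        loaded = yaml.safe_load(sidecar_path.read_text())
        return dict(loaded) if loaded else {}
    return {}
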