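"""Weighted structural connectivity matrices: I/O, validation,
normalization, and a synthetic generator.

Connection weights are mean fractional anisotropy (FA) values along
tracts linking two cortical regions, hence dimensionless numbers in
[0, 1].  The default layout mirrors a bilateral 66-region gyral
parcellation: 33 regions per hemisphere, with denser and stronger
intra-hemispheric blocks and boosted homotopic (i, i + n/2) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative zero-diagonal weight matrix with ROI labels."""

    weights: np.ndarray
    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]  # "L" / "R" per region

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"matrix must be square, got shape {W.shape}")
        n = W.shape[0]
        if len(self.labels) != n or len(self.hemispheres) != n:
            raise ValueError("labels/hemispheres length must match matrix size")
        bad = np.argwhere(~np.isfinite(W))
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"non-finite entry at ({self.labels[i]}, {self.labels[j]})")
        bad = np.argwhere(W < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"negative weight at ({self.labels[i]}, {self.labels[j]})")
        bad = np.argwhere(W > 1)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"weight {W[bad[0][0], bad[0][1]]:.4g} at ({self.labels[i]}, "
                f"{self.labels[j]}) exceeds the FA bound of 1"
            )
        asym = np.max(np.abs(W - W.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"asymmetry {asym:.3e} exceeds tolerance {_SYMMETRY_TOL:.0e}")
        W = 0.5 * (W + W.T)
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "hemispheres", tuple(self.hemispheres))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def density(self) -> float:
        """Fraction of nonzero off-diagonal entries."""
        n = self.n_regions
        off = n * (n - 1)
        return float(np.count_nonzero(self.weights) / off) if off else 0.0


def _default_labels(n: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    half = n // 2
    labels = tuple(f"ROI_{i + 1:02d}_{'L' if i < half else 'R'}" for i in range(n))
    hemis = tuple("L" if i < half else "R" for i in range(n))
    return labels, hemis


def read_matrix(path: str | Path, label_path: str | Path | None = None) -> ConnectivityMatrix:
    """Read a dense TSV/CSV matrix (header row + label column).

    ``label_path`` optionally supplies a two-column (name, hemisphere)
    TSV; otherwise hemispheres are inferred from a trailing _L/_R suffix
    on the labels, defaulting to an even left/right split.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    W = df.to_numpy(dtype=float)
    labels = tuple(str(c) for c in df.columns)
    if label_path is not None:
        tab = pd.read_csv(label_path, sep="\t", header=None, names=["name", "hemisphere"])
        hemis = tuple(str(h) for h in tab["hemisphere"])
    elif all(l.endswith(("_L", "_R")) for l in labels):
        hemis = tuple(l[-1] for l in labels)
    else:
        hemis = _default_labels(len(labels))[1]
    return ConnectivityMatrix(W, labels, hemis)


def write_matrix(cm: ConnectivityMatrix, path: str | Path,
                 label_path: str | Path | None = None) -> None:
    """Write the dense matrix as TSV/CSV; optionally the ROI label table."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(cm.weights, index=list(cm.labels), columns=list(cm.labels)).to_csv(
        path, sep=sep, float_format="%.10g")
    if label_path is not None:
        pd.DataFrame({"name": cm.labels, "hemisphere": cm.hemispheres}).to_csv(
            label_path, sep="\t", header=False, index=False)


def synthesize_connectome(
    n: int = 66,
    seed: int = 0,
    density: float = 0.3,
    weight_mean: float = 0.45,
    weight_shape: float = 8.0,
    intra_hemisphere_boost: float = 0.5,
    homotopic_boost: float = 0.3,
) -> ConnectivityMatrix:
    """Generate an FA-weighted synthetic connectome.

    Weights are Beta-distributed with the given mean and concentration
    (FA is bounded in [0, 1]).  Intra-hemispheric pairs have their
    connection probability and weight scaled up by
    ``1 + intra_hemisphere_boost``; homotopic pairs (i, i + n/2) are
    always connected with weights scaled by ``1 + homotopic_boost``.
    Reproducible given ``seed``.
    """
    if n < 2 or n % 2:
        raise ValueError(f"n must be even and >= 2, got {n}")
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if not 0 < weight_mean < 1:
        raise ValueError("weight_mean must be in (0, 1)")
    rng = np.random.default_rng(seed)
    half = n // 2
    alpha = weight_mean * weight_shape
    beta = (1.0 - weight_mean) * weight_shape
    W = np.zeros((n, n))
    hemi = np.array([0] * half + [1] * half)
    for i in range(n):
        for j in range(i + 1, n):
            intra = hemi[i] == hemi[j]
            homotopic = (j - i) == half and hemi[i] != hemi[j]
            p_conn = min(1.0, density * (1.0 + intra_hemisphere_boost * intra))
            if homotopic or rng.random() < p_conn:
                wgt = rng.beta(alpha, beta)
                if intra:
                    wgt *= 1.0 + intra_hemisphere_boost * 0.2
                if homotopic:
                    wgt *= 1.0 + homotopic_boost
                W[i, j] = W[j, i] = min(wgt, 1.0)
    labels, hemis = _default_labels(n)
    return ConnectivityMatrix(W, labels, hemis)


def normalize(cm: ConnectivityMatrix, mode: str = "spectral") -> tuple[ConnectivityMatrix, float]:
    """Rescale the matrix; returns (matrix, scale) with weights' = weights/scale.

    Modes: ``none`` (identity), ``row_sum`` (max row sum to 1),
    ``spectral`` (spectral radius to 1).  A zero matrix cannot be
    normalized with a non-``none`` mode.
    """
    if mode == "none":
        return cm, 1.0
    W = cm.weights
    if not np.any(W):
        raise ValueError(f"cannot normalize a zero matrix with mode {mode!r}")
    if mode == "row_sum":
        scale = float(np.max(W.sum(axis=1)))
    elif mode == "spectral":
        scale = float(np.max(np.abs(np.linalg.eigvalsh(W))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConnectivityMatrix(W / scale, cm.labels, cm.hemispheres), scale
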