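"""Classification support: spectral band arithmetic and accuracy metrics.

These utilities serve an externally produced land-use classification: the
spectral indices are plain elementwise band arithmetic over reflectance
grids, and classification quality is summarized from a confusion matrix by
overall accuracy and Cohen's kappa,

    p_o = trace / n,     p_e = Σ_i a_i·b_i / n²,     κ = (p_o − p_e)/(1 − p_e)

with a_i the reference (row) and b_i the predicted (column) marginals.
Zero denominators in an index yield masked values, never an exception.
MIR defaults to the SWIR grid when no separate MIR band is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BandSet", "ConfusionMatrix", "spectral_index", "accuracy_metrics", "SPECTRAL_INDICES"]


@dataclass(frozen=True)
class BandSet:
    """Named reflectance grids (same shape; typically in [0, 1])."""

    B: np.ndarray | None = None  # blue
    G: np.ndarray | None = None  # green
    R: np.ndarray | None = None  # red
    NIR: np.ndarray | None = None
    SWIR: np.ndarray | None = None
    MIR: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(v).shape
            for v in (self.B, self.G, self.R, self.NIR, self.SWIR, self.MIR)
            if v is not None
        }
        if len(shapes) > 1:
            raise ValueError(f"band shapes differ: {sorted(shapes)}")

    def get(self, name: str) -> np.ndarray:
        v = getattr(self, name, None)
        if v is None and name == "MIR":
            v = self.SWIR  # MIR falls back to SWIR
        if v is None:
            raise KeyError(f"band {name!r} missing from BandSet")
        return np.asarray(v, dtype=float)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ma.MaskedArray:
    return np.ma.masked_invalid(
        np.divide(num, den, out=np.full_like(num, np.nan, dtype=float), where=den != 0)
    )


#: name -> (required bands, formula)
SPECTRAL_INDICES = {
    "NDVI": (("NIR", "R"), lambda b: _ratio(b.get("NIR") - b.get("R"), b.get("NIR") + b.get("R"))),
    "NDBI": (("SWIR", "NIR"), lambda b: _ratio(b.get("SWIR") - b.get("NIR"), b.get("SWIR") + b.get("NIR"))),
    "MNDWI": (("G", "MIR"), lambda b: _ratio(b.get("G") - b.get("MIR"), b.get("G") + b.get("MIR"))),
    "RVI": (("NIR", "R"), lambda b: _ratio(b.get("NIR"), b.get("R"))),
    "DVI": (("NIR", "R"), lambda b: np.ma.masked_invalid(b.get("NIR") - b.get("R"))),
    "SAVI": (("NIR", "R"), lambda b: _ratio(1.5 * (b.get("NIR") - b.get("R")), b.get("NIR") + b.get("R") + 0.5)),
    "NDMI": (("G", "SWIR"), lambda b: _ratio(b.get("G") - b.get("SWIR"), b.get("G") + b.get("SWIR"))),
    "EVI": (("NIR", "R", "B"), lambda b: _ratio(2.5 * (b.get("NIR") - b.get("R")), b.get("NIR") + 6.0 * b.get("R") - 7.5 * b.get("B") + 1.0)),
}


def spectral_index(bands: BandSet, name: str) -> np.ma.MaskedArray:
    """Evaluate a named spectral index elementwise; zero denominators masked."""
    key = name.upper()
    if key not in SPECTRAL_INDICES:
        raise KeyError(
            f"unknown spectral index {name!r}; known: {sorted(SPECTRAL_INDICES)}"
        )
    required, fn = SPECTRAL_INDICES[key]
    for b in required:
        bands.get(b)  # raises KeyError with the band name if missing
    return fn(bands)


@dataclass(frozen=True)
class ConfusionMatrix:
    """m×m integer counts; rows = reference class, columns = prediction."""

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(m, np.rint(m)):
            raise ValueError("counts must be integers")
        if m.sum() < 1:
            raise ValueError("confusion matrix must contain at least one sample")
        object.__setattr__(self, "counts", m.astype(np.int64))

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), tuple(map(str, df.columns)))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def accuracy_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Overall accuracy p_o, chance agreement p_e and kappa κ.

    When p_e = 1 (degenerate single-cell matrix) kappa is undefined and
    reported as NaN.
    """
    m = cm.counts
    n = cm.n
    p_o = float(np.trace(m)) / n
    a = m.sum(axis=1)  # reference marginals
    b = m.sum(axis=0)  # predicted marginals
    p_e = float((a * b).sum()) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e != 1.0 else float("nan")
    return {"overall_accuracy": p_o, "chance_agreement": p_e, "kappa": kappa}
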