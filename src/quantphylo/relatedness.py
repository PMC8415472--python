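"""Pairwise relatedness measures between number strings.

Three one-number summaries of how related two taxa's number strings are:

* **correlation** — the lag-0 Pearson product-moment correlation between the
  two strings (+1 perfect synchrony, −1 exact mirror images, 0 no linear
  relation).  A lag-m autocorrelation of a single string is also provided.
* **average mutual information (AMI)** — MI = H(X) + H(Y) − H(X,Y) with
  plug-in Shannon entropies, treating each distinct encoded value (including
  the gap value 0) as a categorical symbol.  Natural-log units by default.
* **box-counting dimension** — the 2-D scatter of one string against the
  other is binned into a 10×10 grid spanning the common value range on both
  axes; the dimension is log(occupied cells)/log(10), between 0 and 2.
  Values near 1 indicate near-identity (points on the diagonal); values near
  2 indicate independence (points filling the square).

Aggregation across properties yields Table-style symmetric matrices of
(mean, sd) per taxon pair.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .properties import (
    BOXDIM_PROPERTIES,
    DEFAULT_PROPERTIES,
    EncodedSequence,
)

__all__ = [
    "RelatednessMatrix",
    "lag_autocorrelation",
    "pair_correlation",
    "average_mutual_information",
    "box_counting_dimension",
    "relatedness_table",
]

MEASURES = ("correlation", "ami", "box_dimension")


def _as_array(x) -> np.ndarray:
    if isinstance(x, EncodedSequence):
        return x.as_array()
    return np.asarray(x, dtype=float)


def lag_autocorrelation(x, m: int) -> float:
    """Lag-m autocorrelation R_m of a single number string.

    R_m = Σ_{t=1}^{N−m} (x_t − x̄)(x_{t+m} − x̄) / Σ_{t=1}^{N} (x_t − x̄)²,
    with x̄ the overall mean (the 1/N factors of autocovariance and variance
    cancel).  R_0 is identically 1.
    """
    xv = _as_array(x)
    n = len(xv)
    if not 0 <= m < n:
        raise ValueError(f"lag {m} outside [0, {n})")
    xc = xv - xv.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a constant string")
    num = float(np.dot(xc[: n - m], xc[m:]))
    return num / denom


def pair_correlation(x, y) -> float:
    """Lag-0 Pearson correlation between two number strings."""
    xv, yv = _as_array(x), _as_array(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < 3:
        raise ValueError("need at least 3 positions")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sx, sy = float(np.dot(xc, xc)), float(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant string")
    r = float(np.dot(xc, yc)) / np.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def _entropy(counts: np.ndarray, base: float | None) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def average_mutual_information(x, y, units: str = "nats") -> float:
    """Plug-in mutual information between two number strings.

    Each distinct encoded value (gap 0 included) is one categorical symbol;
    the joint empirical frequency table over aligned positions gives
    MI = H(X) + H(Y) − H(X,Y).  ``units`` is ``"nats"`` (default) or
    ``"bits"``.
    """
    xv, yv = _as_array(x), _as_array(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) == 0:
        raise ValueError("empty input")
    if units not in ("nats", "bits"):
        raise ValueError(f"units must be 'nats' or 'bits', got {units!r}")
    base = 2.0 if units == "bits" else None
    joint = Counter(zip(xv.tolist(), yv.tolist()))
    jc = np.array(list(joint.values()), dtype=float)
    xc = np.array(list(Counter(xv.tolist()).values()), dtype=float)
    yc = np.array(list(Counter(yv.tolist()).values()), dtype=float)
    mi = _entropy(xc, base) + _entropy(yc, base) - _entropy(jc, base)
    return max(0.0, mi)


def box_counting_dimension(
    x, y, grid: int = 10, average_offsets: bool = False
) -> float:
    """Box-counting dimension of the 2-D scatter of two number strings.

    Both axes span the common range [min of all values, max of all values],
    divided into ``grid`` equal half-open bins (the last bin closed).  The
    dimension is log(occupied cells)/log(grid).

    With ``average_offsets`` the occupied-cell count is averaged over a 5×5
    lattice of sub-cell grid shifts, mitigating quantization error from
    arbitrary grid placement; off by default.
    """
    xv, yv = _as_array(x), _as_array(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) == 0:
        raise ValueError("empty input")
    lo = float(min(xv.min(), yv.min()))
    hi = float(max(xv.max(), yv.max()))
    if hi == lo:
        warnings.warn("zero value range; box dimension set to 0 by convention")
        return 0.0
    cell = (hi - lo) / grid

    def n_occupied(offset: float) -> int:
        # offset shifts the grid origin by a fraction of one cell; points
        # below the shifted origin fall in bin 0, beyond the end in the last
        ix = np.floor((xv - lo) / cell - offset).astype(int).clip(0, grid - 1)
        iy = np.floor((yv - lo) / cell - offset).astype(int).clip(0, grid - 1)
        return len(set(zip(ix.tolist(), iy.tolist())))

    if average_offsets:
        offsets = [i / 5.0 for i in range(5)]
        n_occ = float(np.mean([n_occupied(o) for o in offsets]))
    else:
        n_occ = float(n_occupied(0.0))
    return float(np.log(n_occ) / np.log(grid))


@dataclass(frozen=True)
class RelatednessMatrix:
    """Symmetric taxon×taxon (mean, sd) matrices for one measure,
    aggregated across properties."""

    measure: str
    labels: Tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    properties_used: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    def cell(self, a: str, b: str) -> Tuple[float, float]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.mean[i, j]), float(self.sd[i, j])

    def to_tsv(self) -> str:
        """Upper-triangle layout with 'mean ± sd' cells."""
        buf = io.StringIO()
        buf.write("\t" + "\t".join(self.labels) + "\n")
        n = len(self.labels)
        for i in range(n):
            cells = []
            for j in range(n):
                if j <= i:
                    cells.append("")
                else:
                    cells.append(f"{self.mean[i, j]:.3f} ± {self.sd[i, j]:.3f}")
            buf.write(self.labels[i] + "\t" + "\t".join(cells) + "\n")
        return buf.getvalue()

    def to_long_tsv(self, per_property: Mapping[Tuple[str, str, str], float]) -> str:
        buf = io.StringIO()
        buf.write("taxon_a\ttaxon_b\tproperty\tvalue\n")
        for (a, b, prop), v in per_property.items():
            buf.write(f"{a}\t{b}\t{prop}\t{v!r}\n")
        return buf.getvalue()


def _measure_fn(measure: str):
    if measure == "correlation":
        return pair_correlation
    if measure == "ami":
        return average_mutual_information
    if measure == "box_dimension":
        return box_counting_dimension
    raise ValueError(f"unknown measure {measure!r}; valid: {MEASURES}")


def relatedness_table(
    encoded: Mapping[Tuple[str, str], EncodedSequence],
    measure: str,
    properties: Iterable[str] | None = None,
) -> RelatednessMatrix:
    """Aggregate one pairwise measure across properties into a matrix.

    For each taxon pair the measure is computed once per property; the cell
    holds the mean and sample (n−1) standard deviation across properties.
    Default property sets: the five encoding defaults for correlation and
    AMI, and volume / pI / solubility for the box dimension.
    """
    fn = _measure_fn(measure)
    if properties is None:
        properties = (
            BOXDIM_PROPERTIES if measure == "box_dimension" else DEFAULT_PROPERTIES
        )
    properties = tuple(properties)
    taxa: List[str] = []
    for (t, _p) in encoded:
        if t not in taxa:
            taxa.append(t)
    for t in taxa:
        for p in properties:
            if (t, p) not in encoded:
                raise KeyError(f"missing encoded sequence for ({t!r}, {p!r})")
    n = len(taxa)
    mean = np.zeros((n, n))
    sd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = np.array(
                [
                    fn(encoded[(taxa[i], p)], encoded[(taxa[j], p)])
                    for p in properties
                ]
            )
            mean[i, j] = mean[j, i] = vals.mean()
            sd[i, j] = sd[j, i] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    if measure == "correlation":
        np.fill_diagonal(mean, 1.0)
    elif measure == "box_dimension":
        pass  # self-dimension depends on the string; leave diagonal at 0
    return RelatednessMatrix(measure, tuple(taxa), mean, sd, properties)
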