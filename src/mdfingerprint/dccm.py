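"""Dynamic cross-correlation matrices and temperature differencing.

The normalized cross-correlation of residues i and j is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with dr_i(t) the displacement of residue i's C-alpha from its trajectory
mean after rigid-body superposition (two-pass fit to the mean structure).
C_ij lies in [-1, 1]: +1 for perfectly correlated motion, -1 for
equal-and-opposite, 0 for independent.  The temperature difference map
dCC = CC_cold - CC_hot (sign configurable) highlights couplings gained or
lost on cooling; contiguous blocks exceeding a threshold are summarized by
:func:`threshold_report`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Selection, Topology, Trajectory
from .flexibility import kabsch_superpose

__all__ = [
    "CorrelationMatrix",
    "DeltaCCMap",
    "dccm",
    "delta_ccm",
    "region_coupling",
    "threshold_report",
]


@dataclass
class CorrelationMatrix:
    """Residue-residue normalized cross-correlations."""

    residues: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.residues)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue list")

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], atol=atol):
            raise AssertionError("correlation matrix is not symmetric")
        d = np.diag(v)
        if not np.allclose(d[np.isfinite(d)], 1.0, atol=atol):
            raise AssertionError("diagonal is not unity")
        if np.any(np.abs(v[finite]) > 1.0 + 1e-9):
            raise AssertionError("|C_ij| exceeds 1")


@dataclass
class DeltaCCMap:
    """Element-wise difference of two correlation matrices; ``label`` names
    which input is the minuend."""

    residues: list[tuple[str, int]]
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        n = len(self.residues)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue list")
        finite = np.isfinite(self.values)
        if np.any(np.abs(self.values[finite]) > 2.0 + 1e-9):
            raise ValueError("delta-CC values must lie in [-2, 2]")


def dccm(topology: Topology, traj: Trajectory,
         ca_selection: Selection | None = None,
         fit: bool = True) -> CorrelationMatrix:
    """Cross-correlation matrix over C-alpha displacements.

    Frames are superposed on the mean structure of the selection (two-pass)
    unless ``fit=False``.  The diagonal is exactly 1; residues with zero
    displacement variance get NaN rows/columns with a warning.
    """
    a = topology.atoms
    if ca_selection is None:
        mask = (a["name"] == "CA").to_numpy() \
            & (a["segment"] == "protein").to_numpy()
        ca_selection = Selection(np.flatnonzero(mask), label="protein CA")
    idx = ca_selection.atom_indices
    if len(idx) < 2:
        raise ValueError("need at least 2 C-alpha atoms")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    residues = [(a.at[int(i), "chain"], int(a.at[int(i), "resid"]))
                for i in idx]
    if len(set(residues)) != len(residues):
        raise ValueError("selection contains more than one atom per residue")

    x = traj.coordinates[:, idx, :].astype(float)
    if fit:
        ref = x[0]
        for _pass in range(2):
            for f in range(x.shape[0]):
                res = kabsch_superpose(x[f], ref)
                x[f] = res.transform(x[f])
            ref = x.mean(axis=0)
    mean = x.mean(axis=0)
    d = x - mean
    n_frames = d.shape[0]
    cov = np.einsum("fid,fjd->ij", d, d) / n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} residues have zero displacement "
                      "variance; their correlations are undefined (NaN)",
                      stacklevel=2)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cov / denom, np.nan)
    c = (c + c.T) / 2.0  # enforce exact symmetry against fp round-off
    np.fill_diagonal(c, 1.0)
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    np.clip(c, -1.0, 1.0, out=c)
    return CorrelationMatrix(residues=residues, values=c)


def delta_ccm(cc_cold: CorrelationMatrix, cc_hot: CorrelationMatrix,
              sign: str = "cold-hot") -> DeltaCCMap:
    """Difference map between two temperatures.

    ``sign='cold-hot'`` (default) computes CC_cold - CC_hot;
    ``sign='hot-cold'`` flips it.  Residue orders must match exactly.
    """
    if cc_cold.residues != cc_hot.residues:
        raise ValueError("residue orders differ between matrices")
    if sign == "cold-hot":
        v = cc_cold.values - cc_hot.values
    elif sign == "hot-cold":
        v = cc_hot.values - cc_cold.values
    else:
        raise ValueError("sign must be 'cold-hot' or 'hot-cold'")
    np.fill_diagonal(v, 0.0)
    return DeltaCCMap(residues=list(cc_cold.residues), values=v, label=sign)


def region_coupling(matrix: CorrelationMatrix | DeltaCCMap,
                    region: tuple[int, int],
                    chain: str | None = None) -> pd.DataFrame:
    """Mean coupling of every outside residue to a residue range.

    ``region`` is an inclusive author-numbering range (e.g. (660, 670));
    the region's self-block is excluded.  Returns a table of
    (chain, resid, mean_coupling) for residues outside the region.
    """
    lo, hi = region
    in_region = np.array([
        lo <= rid <= hi and (chain is None or ch == chain)
        for ch, rid in matrix.residues])
    if not in_region.any():
        raise ValueError(f"no residues in region {lo}-{hi}")
    rows = []
    v = matrix.values
    for j, (ch, rid) in enumerate(matrix.residues):
        if in_region[j]:
            continue
        vals = v[in_region, j]
        rows.append(dict(chain=ch, resid=rid,
                         mean_coupling=float(np.nanmean(vals))))
    return pd.DataFrame(rows, columns=["chain", "resid", "mean_coupling"])


def threshold_report(dcc: DeltaCCMap, pos_threshold: float = 0.5,
                     neg_threshold: float = -0.5) -> pd.DataFrame:
    """Contiguous residue-range blocks whose dCC exceeds a threshold.

    Cells above ``pos_threshold`` (or below ``neg_threshold``) are grouped
    into 4-connected components on the matrix grid; each component is
    reported as its bounding residue ranges with the mean dCC inside.
    Only the upper triangle is scanned (the map is symmetric).
    """
    if not (pos_threshold > 0 > neg_threshold):
        raise ValueError("thresholds must satisfy pos > 0 > neg")
    v = dcc.values
    resids = [rid for _, rid in dcc.residues]
    rows = []
    upper = np.triu(np.ones_like(v, dtype=bool), k=1)
    for sign, mask in (("+", (v > pos_threshold) & upper),
                       ("-", (v < neg_threshold) & upper)):
        labels, n_blobs = ndimage.label(mask)
        for b in range(1, n_blobs + 1):
            ii, jj = np.nonzero(labels == b)
            rows.append(dict(
                sign=sign,
                range_i=f"{resids[ii.min()]}-{resids[ii.max()]}",
                range_j=f"{resids[jj.min()]}-{resids[jj.max()]}",
                n_cells=len(ii),
                mean_delta_cc=float(v[ii, jj].mean()),
            ))
    return pd.DataFrame(rows, columns=["sign", "range_i", "range_j",
                                       "n_cells", "mean_delta_cc"])
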