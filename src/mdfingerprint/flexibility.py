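"""Rigid-body superposition, RMSD time series, per-residue RMSF and
temperature differencing.

The flexibility fingerprint of a trajectory pair (cold vs. hot) is the
per-residue change in root-mean-square fluctuation, Delta-RMSF = RMSF_hot -
RMSF_cold.  RMSF here follows the standard two-pass definition: frames are
first aligned to frame 0 on a fitting selection (C-alpha by default), the
mean structure is computed, frames are re-aligned to that mean, and the
per-atom RMSF is sqrt(<|r - <r>|^2>).  Per-residue values average over all
atoms of the residue, unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PerResidueProfile, Selection, Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf_profile",
    "delta_rmsf",
]


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference:
    ``x -> (x - mobile_centroid) @ rotation.T + reference_centroid``."""

    rotation: np.ndarray
    translation: np.ndarray  # reference_centroid - rotated mobile_centroid
    rmsd: float
    mobile_centroid: np.ndarray = field(default=None, repr=False)
    reference_centroid: np.ndarray = field(default=None, repr=False)

    def transform(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.mobile_centroid) @ self.rotation.T \
            + self.reference_centroid


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> SuperpositionResult:
    """Optimal proper rotation + translation (Kabsch, via SVD) minimizing
    the weighted RMSD of ``mobile`` onto ``reference``.

    Reflections are suppressed: the returned rotation always has
    determinant +1.  Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    cm = wn @ mob
    cr = wn @ ref
    x = mob - cm
    y = ref - cr
    h = (x * wn[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    # rank < 2 leaves the rotation about the degenerate axis undetermined
    if s[1] < 1e-10 * max(s[0], 1e-30) or s[0] == 0:
        raise ValueError("point sets are collinear or rank-deficient; "
                         "superposition is not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.sum(wn[:, None] * (fitted - y) ** 2)))
    return SuperpositionResult(rotation=rot, translation=cr - rot @ cm,
                               rmsd=rmsd, mobile_centroid=cm,
                               reference_centroid=cr)


def apply_superposition(result: SuperpositionResult,
                        coordinates: np.ndarray) -> np.ndarray:
    return result.transform(coordinates)


def _fit_frames(traj: Trajectory, fit_idx: np.ndarray,
                reference: np.ndarray,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` (coordinates of the fit
    selection) and return the transformed full-frame coordinates."""
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        res = kabsch_superpose(traj.coordinates[f, fit_idx], reference,
                               weights)
        out[f] = res.transform(traj.coordinates[f])
    return out


def rmsd_series(traj: Trajectory, reference_frame: int,
                fit_selection: Selection, measure_selection: Selection,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD after superposing each frame onto a reference frame.

    Fitting uses ``fit_selection``; the deviation is measured over
    ``measure_selection`` (unweighted).  Returns an array of length
    n_frames in angstrom.
    """
    if len(fit_selection) == 0 or len(measure_selection) == 0:
        raise ValueError("selections must be non-empty")
    fit_idx = fit_selection.atom_indices
    mi = measure_selection.atom_indices
    ref_fit = traj.coordinates[reference_frame, fit_idx]
    ref_measure = traj.coordinates[reference_frame, mi]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        res = kabsch_superpose(traj.coordinates[f, fit_idx], ref_fit,
                               weights)
        moved = res.transform(traj.coordinates[f, mi])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_measure) ** 2, axis=1)))
    return out


def rmsf_profile(topology: Topology, traj: Trajectory,
                 fit_selection: Selection,
                 residues: Selection | None = None,
                 frame_range: tuple[int, int] | None = None,
                 mass_weighted_fit: bool = False) -> PerResidueProfile:
    """Per-residue RMSF about the mean structure (two-pass alignment).

    Pass 1 fits every frame to frame 0 on ``fit_selection`` and computes the
    mean structure; pass 2 re-fits to that mean before accumulating
    fluctuations.  ``residues`` restricts which residues are reported (all
    atoms of each covered residue contribute, equally weighted); default is
    every residue intersecting the fit selection's segments.
    """
    if len(fit_selection) == 0:
        raise ValueError("fit selection must be non-empty")
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    if hi - lo < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sub = Trajectory(traj.coordinates[lo:hi], traj.box[lo:hi],
                     traj.frame_times[lo:hi])
    fit_idx = fit_selection.atom_indices
    w = None
    if mass_weighted_fit:
        w = topology.atoms["mass"].to_numpy(dtype=float)[fit_idx]

    aligned = _fit_frames(sub, fit_idx, sub.coordinates[0, fit_idx], w)
    mean1 = aligned.mean(axis=0)
    sub2 = Trajectory(aligned, sub.box, sub.frame_times)
    aligned = _fit_frames(sub2, fit_idx, mean1[fit_idx], w)
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    keep = None
    if residues is not None:
        keep = set()
        rset = set(residues.atom_indices.tolist())
        for rid, idx in topology.residues():
            if rset.intersection(idx.tolist()):
                keep.add(rid)
    rows = []
    for rid, idx in topology.residues():
        if keep is not None and rid not in keep:
            continue
        rows.append(dict(chain=rid[0], resid=rid[1],
                         value=float(per_atom[idx].mean())))
    prof = PerResidueProfile(pd.DataFrame(rows), "rmsf",
                             metadata=dict(frame_range=(lo, hi),
                                           n_frames=hi - lo,
                                           fit_label=fit_selection.label))
    return prof


def delta_rmsf(profile_hot: PerResidueProfile,
               profile_cold: PerResidueProfile) -> PerResidueProfile:
    """Hot minus cold per-residue RMSF difference (sign fixed as
    hot - cold, i.e. 323 K - 273 K in the two-temperature protocol)."""
    for p in (profile_hot, profile_cold):
        if p.value_kind != "rmsf":
            raise ValueError("inputs must be RMSF profiles")
    hot = profile_hot.as_dict()
    cold = profile_cold.as_dict()
    if set(hot) != set(cold):
        diff = sorted(set(hot).symmetric_difference(cold))
        raise ValueError(f"residue sets differ: {diff[:10]}"
                         + ("..." if len(diff) > 10 else ""))
    rows = [dict(chain=rid[0], resid=rid[1], value=hot[rid] - cold[rid])
            for rid in profile_hot.residue_ids()]
    return PerResidueProfile(pd.DataFrame(rows), "delta_rmsf",
                             metadata=dict(sign="hot-minus-cold"))
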