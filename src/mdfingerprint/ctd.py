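"""C-terminal-domain conformational tracking: helix/coil timelines and
domain-membrane displacement.

Secondary structure is assigned from backbone dihedrals alone: a residue is
alpha-helical (H) when its (phi, psi) falls inside a window around the
canonical helix values (-57, -47) +/- 30 degrees AND it belongs to a run of
at least ``min_run`` consecutive in-window residues; everything else,
including chain termini with undefined dihedrals, is coil (C).  This
deliberately binary, deterministic assignment is sufficient to track a
helix-to-coil transition without a full DSSP/STRIDE pattern analysis.

Domain detachment from the membrane is measured as the absolute difference
of mass-weighted z centers of mass, with domain atoms imaged to the
periodic copy nearest the membrane before averaging.  A two-segment
(flat-then-linear) least-squares fit locates the detachment frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Selection, Topology, Trajectory

__all__ = [
    "HELIX_WINDOW",
    "SecondaryStructureTimeline",
    "DomainDistanceSeries",
    "dihedral",
    "backbone_dihedrals",
    "assign_ss",
    "ss_timeline",
    "helix_fraction",
    "domain_membrane_distance",
    "detect_detachment",
    "build_backbone_from_dihedrals",
]

#: (phi0, psi0, half-width) of the alpha-helix dihedral window, degrees
HELIX_WINDOW = (-57.0, -47.0, 30.0)
MIN_HELIX_RUN = 4


@dataclass
class SecondaryStructureTimeline:
    """H/C labels, frames x residues."""

    residues: list[tuple[str, int]]
    labels: np.ndarray  # dtype '<U1', shape (n_frames, n_residues)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape[1] != len(self.residues):
            raise ValueError("label columns must match residue list")
        bad = set(np.unique(self.labels)) - {"H", "C"}
        if bad:
            raise ValueError(f"unexpected labels {bad}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass
class DomainDistanceSeries:
    """Per-frame |z_COM(domain) - z_COM(membrane)| in angstrom."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must align")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------- #
# dihedral machinery

def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_indices(topology: Topology,
                      residue_range: tuple[int, int] | None = None,
                      chain: str | None = None,
                      ) -> list[tuple[tuple[str, int], dict[str, int]]]:
    a = topology.atoms
    out = []
    for rid, idx in topology.residues():
        ch, resid = rid
        if chain is not None and ch != chain:
            continue
        if residue_range is not None and not (
                residue_range[0] <= resid <= residue_range[1]):
            continue
        names = {a.at[int(i), "name"]: int(i) for i in idx}
        out.append((rid, {k: names[k] for k in ("N", "CA", "C")
                          if k in names}))
    return out


def backbone_dihedrals(frame: np.ndarray,
                       backbone: list[tuple[tuple[str, int], dict]],
                       ) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where the flanking residue or a
    backbone atom is missing."""
    n = len(backbone)
    out = []
    for i, (rid, atoms) in enumerate(backbone):
        phi = psi = None
        complete = all(k in atoms for k in ("N", "CA", "C"))
        if complete and i > 0 and "C" in backbone[i - 1][1]:
            phi = dihedral(frame[backbone[i - 1][1]["C"]],
                           frame[atoms["N"]], frame[atoms["CA"]],
                           frame[atoms["C"]])
        if complete and i < n - 1 and "N" in backbone[i + 1][1]:
            psi = dihedral(frame[atoms["N"]], frame[atoms["CA"]],
                           frame[atoms["C"]],
                           frame[backbone[i + 1][1]["N"]])
        out.append((phi, psi))
    return out


def _angular_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def assign_ss(frame: np.ndarray, topology: Topology,
              residue_range: tuple[int, int] | None = None,
              chain: str | None = None,
              window: tuple[float, float, float] = HELIX_WINDOW,
              min_run: int = MIN_HELIX_RUN,
              ) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Per-residue H/C labels for one frame.

    A residue is H when (phi, psi) falls inside the helix window and it sits
    in a run of at least ``min_run`` consecutive in-window residues.
    Residues with undefined phi or psi (chain termini, missing backbone
    atoms) are C.
    """
    backbone = _backbone_indices(topology, residue_range, chain)
    if not backbone:
        raise ValueError("no residues with backbone atoms in range")
    incomplete = [rid for rid, atoms in backbone
                  if not all(k in atoms for k in ("N", "CA", "C"))]
    if incomplete:
        warnings.warn(f"residues missing backbone atoms labeled C: "
                      f"{incomplete[:5]}", stacklevel=2)
    phi0, psi0, half = window
    dih = backbone_dihedrals(frame, backbone)
    in_window = np.array([
        phi is not None and psi is not None
        and _angular_diff(phi, phi0) <= half
        and _angular_diff(psi, psi0) <= half
        for phi, psi in dih])
    labels = np.full(len(backbone), "C", dtype="<U1")
    run_start = None
    for i in range(len(in_window) + 1):
        inside = i < len(in_window) and in_window[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            if i - run_start >= min_run:
                labels[run_start:i] = "H"
            run_start = None
    return [rid for rid, _ in backbone], labels


def ss_timeline(topology: Topology, traj: Trajectory,
                residue_range: tuple[int, int] | None = None,
                chain: str | None = None,
                window: tuple[float, float, float] = HELIX_WINDOW,
                min_run: int = MIN_HELIX_RUN) -> SecondaryStructureTimeline:
    """Helix/coil assignment for every frame of a trajectory."""
    residues = None
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for f in range(traj.n_frames):
            rids, labels = assign_ss(traj.coordinates[f], topology,
                                     residue_range, chain, window, min_run)
            residues = rids
            rows.append(labels)
    return SecondaryStructureTimeline(residues=residues,
                                      labels=np.stack(rows))


def helix_fraction(timeline: SecondaryStructureTimeline) -> np.ndarray:
    """Fraction of residues labeled H, per frame."""
    return (timeline.labels == "H").mean(axis=1)


# ---------------------------------------------------------------------- #
# domain-membrane displacement

def domain_membrane_distance(topology: Topology, traj: Trajectory,
                             domain: Selection, membrane: Selection,
                             mass_weighted: bool = True,
                             ) -> DomainDistanceSeries:
    """Per-frame |z-COM separation| between a domain and the membrane.

    The membrane z-COM is taken from raw coordinates (the bilayer is assumed
    whole in z); each domain atom is imaged along z to the periodic copy
    nearest the membrane COM before averaging, so a drifting domain is not
    artificially folded back.  Swapping the selections gives the identical
    series.
    """
    if len(domain) == 0 or len(membrane) == 0:
        raise ValueError("selections must be non-empty")
    masses = topology.atoms["mass"].to_numpy(dtype=float)
    wd = masses[domain.atom_indices] if mass_weighted \
        else np.ones(len(domain))
    wm = masses[membrane.atom_indices] if mass_weighted \
        else np.ones(len(membrane))
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        lz = traj.box[f, 2]
        zm = traj.coordinates[f, membrane.atom_indices, 2]
        mem_com = float(np.average(zm, weights=wm))
        zd = traj.coordinates[f, domain.atom_indices, 2]
        dz = zd - mem_com
        dz -= lz * np.round(dz / lz)
        out[f] = abs(float(np.average(dz, weights=wd)))
    return DomainDistanceSeries(values=out, frame_times=traj.frame_times)


def detect_detachment(series: DomainDistanceSeries | np.ndarray,
                      ) -> tuple[int, float]:
    """Change point of a flat-then-drifting distance series.

    Fits, for every candidate split k, a constant on frames [0, k) and a
    straight line on [k, n); returns (k*, slope) minimizing the combined
    squared error.  The slope is in A/frame.
    """
    y = series.values if isinstance(series, DomainDistanceSeries) \
        else np.asarray(series, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("series too short for change-point detection")
    x = np.arange(n, dtype=float)
    best = (None, np.inf, 0.0)
    for k in range(2, n - 2):
        left = y[:k]
        sse_l = float(np.sum((left - left.mean()) ** 2))
        xr, yr = x[k:], y[k:]
        a_mat = np.vstack([xr - xr[0], np.ones(n - k)]).T
        coef, res, *_ = np.linalg.lstsq(a_mat, yr, rcond=None)
        sse_r = float(res[0]) if res.size else float(
            np.sum((a_mat @ coef - yr) ** 2))
        sse = sse_l + sse_r
        if sse < best[1]:
            best = (k, sse, float(coef[0]))
    return best[0], best[2]


# ---------------------------------------------------------------------- #
# ideal backbone construction (synthetic-data support)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place_atom(a, b, c, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d from a-b-c."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               -np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_from_dihedrals(n_residues: int, phi: float,
                                  psi: float, omega: float = 180.0,
                                  ) -> np.ndarray:
    """Ideal N/CA/C backbone of a homopolymer at uniform (phi, psi).

    Returns (3 * n_residues, 3) coordinates ordered N, CA, C per residue;
    canonical helix geometry is (phi, psi) = (-57, -47), a fully extended
    strand (-120, +120).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    coords = np.zeros((3 * n_residues, 3))
    coords[0] = (0.0, 0.0, 0.0)                      # N1
    coords[1] = (_BOND_N_CA, 0.0, 0.0)               # CA1
    ang = np.deg2rad(_ANG_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])            # C1
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = coords[3 * i - 3: 3 * i]
        # N_i from psi of the previous residue
        coords[3 * i] = _place_atom(n_prev, ca_prev, c_prev,
                                    _BOND_C_N, _ANG_CA_C_N, psi)
        # CA_i from omega
        coords[3 * i + 1] = _place_atom(ca_prev, c_prev, coords[3 * i],
                                        _BOND_N_CA, _ANG_C_N_CA, omega)
        # C_i from phi
        coords[3 * i + 2] = _place_atom(c_prev, coords[3 * i],
                                        coords[3 * i + 1],
                                        _BOND_CA_C, _ANG_N_CA_C, phi)
    return coords
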