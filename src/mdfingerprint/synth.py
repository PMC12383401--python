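"""Synthetic trajectory generators with known ground truth.

Real production trajectories of membrane transporters run to hundreds of
nanoseconds and are rarely redistributable, so every analysis stage in this
package is validated against small synthetic systems whose statistical
structure is planted by construction:

* a Gaussian network of pseudo-C-alpha atoms with a prescribed 3N x 3N
  displacement covariance (ground truth for RMSF and cross-correlation
  recovery),
* a bilayer of rigid-rod acyl chains with a prescribed tilt-angle
  distribution (closed-form S_CD),
* donor-H-acceptor triplets toggled between bonded and broken geometry by
  independent Bernoulli draws (planted hydrogen-bond occupancy),
* a compact domain that detaches from a membrane slab and drifts at a fixed
  rate (planted change point and displacement),
* a tiny receptor-ligand "complex" whose Coulomb/LJ/GB energies are
  hand-computable.

Every generator is bit-reproducible under a fixed seed and returns the
planted ground truth alongside the data, so recovery tests never re-derive
truth from the very arrays they are checking.  ``save_bundle`` writes
PDB + DCD plus a JSON sidecar carrying the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Topology, Trajectory, write_structure, write_trajectory

__all__ = [
    "GaussianNetSpec",
    "BilayerSpec",
    "HBondPlantSpec",
    "make_gaussian_network_traj",
    "make_bilayer_traj",
    "make_hbond_traj",
    "make_domain_drift_traj",
    "make_toy_complex",
    "covariance_from_residue_correlation",
    "make_helix_coil_traj",
    "save_bundle",
]

_BIG_BOX = 500.0  # effectively open boundaries for non-membrane toys


def _atom_row(name, element, resid, resname, chain, segment, mass,
              charge=np.nan, eps=np.nan, rmin=np.nan, born=np.nan):
    return dict(name=name, element=element, resid=resid, resname=resname,
                chain=chain, segment=segment, mass=mass, charge=charge,
                lj_epsilon=eps, lj_rmin_half=rmin, born_radius=born)


# ---------------------------------------------------------------------- #
# Gaussian network

@dataclass
class GaussianNetSpec:
    """Multivariate-normal fluctuations of pseudo-C-alpha atoms.

    ``covariance`` is the full (3n x 3n) displacement covariance in A^2,
    ordered atom-major (x1, y1, z1, x2, ...).  ``mean_structure`` defaults
    to an extended chain with 3.8 A spacing.
    """

    n_residues: int
    covariance: np.ndarray
    n_frames: int = 1000
    seed: int = 0
    mean_structure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = 3 * self.n_residues
        if self.covariance.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError(
                f"covariance is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})")
        if self.mean_structure is None:
            # loose helical CA trace (non-collinear, so rigid-body fits
            # are well defined): radius 2.3 A, rise 1.5 A, 100 deg/residue
            k = np.arange(self.n_residues)
            ang = np.deg2rad(100.0) * k
            self.mean_structure = np.stack(
                [2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * k], axis=1)
        else:
            self.mean_structure = np.asarray(self.mean_structure, float)
            if self.mean_structure.shape != (self.n_residues, 3):
                raise ValueError("mean_structure must be (n_residues, 3)")


def covariance_from_residue_correlation(corr: np.ndarray,
                                        sigma: float = 1.0) -> np.ndarray:
    """Expand an n x n residue correlation matrix into the 3n x 3n
    displacement covariance ``sigma^2 * corr (x) I3`` (isotropic blocks).

    With isotropic blocks the normalized cross-correlation of residues i, j
    equals ``corr[i, j]`` exactly in expectation, so the input doubles as the
    planted truth for cross-correlation recovery.
    """
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    return sigma ** 2 * np.kron(corr, np.eye(3))


def make_gaussian_network_traj(spec: GaussianNetSpec,
                               ) -> tuple[Topology, Trajectory, dict]:
    """Draw frames from the planted multivariate normal.

    Returns (topology, trajectory, ground_truth); ground truth carries the
    planted covariance and the per-coordinate standard deviations.
    """
    rng = np.random.default_rng(spec.seed)
    d = 3 * spec.n_residues
    # eigen-decomposition sampling tolerates PSD-degenerate covariances
    w, v = np.linalg.eigh(spec.covariance)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((spec.n_frames, d))
    disp = z @ (v * np.sqrt(w)).T
    coords = spec.mean_structure[None, :, :] + disp.reshape(
        spec.n_frames, spec.n_residues, 3)

    rows = [_atom_row("CA", "C", i + 1, "ALA", "A", "protein", 12.011)
            for i in range(spec.n_residues)]
    top = Topology(pd.DataFrame(rows))
    box = np.full((spec.n_frames, 3), _BIG_BOX)
    times = np.arange(spec.n_frames, dtype=float)
    traj = Trajectory(coords, box, times)
    truth = {
        "generator": "gaussian_network",
        "seed": spec.seed,
        "n_residues": spec.n_residues,
        "n_frames": spec.n_frames,
        "covariance": spec.covariance.tolist(),
    }
    return top, traj, truth


# ---------------------------------------------------------------------- #
# bilayer with planted tilt distribution

@dataclass
class BilayerSpec:
    """Rigid-rod acyl chains with a planted tilt-angle distribution.

    Each lipid carries a phosphorus headgroup bead and two straight chains
    (sn-1 carbons named C31..C3n, sn-2 named C21..C2n, CHARMM-style).  The
    tilt angle theta of each chain relative to the membrane normal (+z for
    the upper leaflet) is redrawn independently per chain and per frame:

    * ``("fixed_angle", theta0_deg)`` — deterministic tilt, expected
      S_CD = (3 cos^2 theta0 - 1)/2 at every carbon;
    * ``("isotropic",)`` — directions uniform on the hemisphere,
      <cos^2 theta> = 1/3, expected S_CD = 0;
    * ``("wrapped_gaussian", mu_deg, sigma_deg)`` — tilt drawn normal and
      reflected into [0, 180].
    """

    n_lipids_per_leaflet: int = 16
    chain_length: int = 12
    tilt_distribution: tuple = ("fixed_angle", 0.0)
    headgroup_z: float = 20.0
    n_frames: int = 100
    seed: int = 0
    cc_spacing: float = 1.27  # carbon-carbon projection along the rod, A

    def __post_init__(self) -> None:
        if self.chain_length < 3:
            raise ValueError("chain_length must be >= 3")
        kinds = {"fixed_angle", "isotropic", "wrapped_gaussian"}
        if self.tilt_distribution[0] not in kinds:
            raise ValueError(f"unknown tilt distribution "
                             f"{self.tilt_distribution[0]!r}")


def _draw_tilt(spec: BilayerSpec, rng: np.random.Generator,
               size: int) -> np.ndarray:
    kind = spec.tilt_distribution[0]
    if kind == "fixed_angle":
        theta = np.full(size, np.deg2rad(spec.tilt_distribution[1]))
    elif kind == "isotropic":
        # uniform direction on the hemisphere: cos(theta) ~ U(0, 1)
        theta = np.arccos(rng.uniform(0.0, 1.0, size))
    else:
        mu, sigma = spec.tilt_distribution[1], spec.tilt_distribution[2]
        theta = np.deg2rad(rng.normal(mu, sigma, size))
        theta = np.abs(theta)
        theta = np.where(theta > np.pi, 2 * np.pi - theta, theta)
    return theta


def make_bilayer_traj(spec: BilayerSpec) -> tuple[Topology, Trajectory, dict]:
    """Build the planted-tilt bilayer; leaflets mirrored in z."""
    rng = np.random.default_rng(spec.seed)
    n_side = int(np.ceil(np.sqrt(spec.n_lipids_per_leaflet)))
    pitch = 10.0
    margin = spec.cc_spacing * spec.chain_length + 10.0
    box_xy = n_side * pitch + 2 * margin
    box_z = 2 * (spec.headgroup_z + 10.0)

    rows = []
    head_xy = []
    n_lip = spec.n_lipids_per_leaflet
    for leaflet, zsign in ((0, 1.0), (1, -1.0)):
        for li in range(n_lip):
            gx, gy = divmod(li, n_side)
            x = margin + gx * pitch
            y = margin + gy * pitch
            head_xy.append((x, y, zsign))
            resid = leaflet * n_lip + li + 1
            rows.append(_atom_row("P", "P", resid, "POPC", "L", "lipid",
                                  30.974))
            for chain_prefix in ("C3", "C2"):  # sn-1, sn-2
                for k in range(1, spec.chain_length + 1):
                    rows.append(_atom_row(f"{chain_prefix}{k}", "C", resid,
                                          "POPC", "L", "lipid", 12.011))
    top = Topology(pd.DataFrame(rows))

    n_atoms = top.n_atoms
    atoms_per_lipid = 1 + 2 * spec.chain_length
    coords = np.empty((spec.n_frames, n_atoms, 3))
    total_chains = 2 * n_lip * 2  # leaflets x lipids x chains
    ks = np.arange(spec.chain_length)
    for f in range(spec.n_frames):
        theta = _draw_tilt(spec, rng, total_chains)
        phi = rng.uniform(0.0, 2 * np.pi, total_chains)
        ci = 0
        ai = 0
        for (x, y, zsign) in head_xy:
            z0 = zsign * spec.headgroup_z
            coords[f, ai] = (x, y, z0)
            ai += 1
            for _chain in range(2):
                t, p = theta[ci], phi[ci]
                ci += 1
                # rod axis pointing from the headgroup toward the midplane
                axis = np.array([np.sin(t) * np.cos(p),
                                 np.sin(t) * np.sin(p),
                                 -zsign * np.cos(t)])
                start = np.array([x, y, z0 - zsign * 1.5])
                pos = start[None, :] + spec.cc_spacing * ks[:, None] * axis
                coords[f, ai:ai + spec.chain_length] = pos
                ai += spec.chain_length
    box = np.tile([box_xy, box_xy, box_z], (spec.n_frames, 1))
    times = np.arange(spec.n_frames, dtype=float)
    traj = Trajectory(coords, box, times)

    kind = spec.tilt_distribution[0]
    if kind == "fixed_angle":
        c2 = float(np.cos(np.deg2rad(spec.tilt_distribution[1])) ** 2)
    elif kind == "isotropic":
        c2 = 1.0 / 3.0
    else:
        c2 = None  # no closed form needed for the wrapped gaussian
    truth = {
        "generator": "bilayer",
        "seed": spec.seed,
        "tilt_distribution": list(spec.tilt_distribution),
        "chain_length": spec.chain_length,
        "n_lipids": 2 * n_lip,
        "n_frames": spec.n_frames,
        "expected_cos2": c2,
        "expected_scd": None if c2 is None else (3 * c2 - 1) / 2,
    }
    return top, traj, truth


# ---------------------------------------------------------------------- #
# planted hydrogen bonds

@dataclass
class HBondPlantSpec:
    """Donor-H-acceptor triplets toggled by Bernoulli draws.

    ``pairs`` lists (donor_name, hydrogen_name, acceptor_name, occupancy);
    geometry tuples are (donor-acceptor distance A, D-H-A angle deg) for the
    bonded and broken states.  The bonded geometry must satisfy, and the
    broken geometry violate, the default detection criterion
    (D-A <= 3.5 A, angle >= 150 deg).
    """

    pairs: Sequence[tuple[str, str, str, float]]
    bonded_geometry: tuple[float, float] = (2.9, 165.0)
    broken_geometry: tuple[float, float] = (5.5, 120.0)
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (d, a) in (("bonded", self.bonded_geometry),
                             ("broken", self.broken_geometry)):
            if not (0 < d and 0 < a <= 180):
                raise ValueError(f"invalid {name} geometry ({d}, {a})")
        if not (self.bonded_geometry[0] <= 3.5
                and self.bonded_geometry[1] >= 150.0):
            raise ValueError("bonded geometry must satisfy the default "
                             "criterion (D-A <= 3.5 A, angle >= 150 deg)")
        if (self.broken_geometry[0] <= 3.5
                and self.broken_geometry[1] >= 150.0):
            raise ValueError("broken geometry must violate the default "
                             "criterion")
        for p in self.pairs:
            if not 0.0 <= p[3] <= 1.0:
                raise ValueError(f"occupancy {p[3]} outside [0, 1]")


def _acceptor_position(d_da: float, angle_deg: float) -> np.ndarray:
    """Place the acceptor given donor at origin and hydrogen at (1, 0, 0)
    so that |D-A| = d_da and the D-H-A angle matches."""
    a = np.deg2rad(angle_deg)
    # A = H + t * u with u at angle `a` from H->D; solve |A| = d_da
    # |A|^2 = 1 - 2 t cos a + t^2
    disc = np.cos(a) ** 2 - 1.0 + d_da ** 2
    if disc < 0:
        raise ValueError(f"geometry ({d_da}, {angle_deg}) is unrealizable")
    t = np.cos(a) + np.sqrt(disc)
    u = np.array([-np.cos(a), np.sin(a), 0.0])
    return np.array([1.0, 0.0, 0.0]) + t * u


def make_hbond_traj(spec: HBondPlantSpec) -> tuple[Topology, Trajectory, dict]:
    """Toggle each triplet between bonded and broken geometry with
    independent per-frame Bernoulli(p) draws; realized occupancies are
    recorded in the ground truth."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    offsets = []
    for i, (dn, hn, an, _p) in enumerate(spec.pairs):
        resid = i + 1
        rows.append(_atom_row(dn, "N", resid, "DON", "A", "protein", 14.007))
        rows.append(_atom_row(hn, "H", resid, "DON", "A", "protein", 1.008))
        rows.append(_atom_row(an, "O", resid, "ACC", "B", "protein", 15.999))
        offsets.append(np.array([20.0 * i, 0.0, 0.0]))
    top = Topology(pd.DataFrame(rows))

    a_bond = _acceptor_position(*spec.bonded_geometry)
    a_free = _acceptor_position(*spec.broken_geometry)
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    realized = []
    for i, (dn, hn, an, p) in enumerate(spec.pairs):
        on = rng.random(spec.n_frames) < p
        realized.append(float(on.mean()))
        base = offsets[i]
        coords[:, 3 * i + 0] = base
        coords[:, 3 * i + 1] = base + np.array([1.0, 0.0, 0.0])
        acc = np.where(on[:, None], a_bond[None, :], a_free[None, :])
        coords[:, 3 * i + 2] = base[None, :] + acc
    box = np.full((spec.n_frames, 3), _BIG_BOX)
    times = np.arange(spec.n_frames, dtype=float)
    traj = Trajectory(coords, box, times)
    truth = {
        "generator": "hbond_plant",
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "pairs": [list(p) for p in spec.pairs],
        "realized_occupancy": realized,
        "bonded_geometry": list(spec.bonded_geometry),
        "broken_geometry": list(spec.broken_geometry),
    }
    return top, traj, truth


# ---------------------------------------------------------------------- #
# detaching domain

def make_domain_drift_traj(n_frames: int = 500, detach_frame: int = 200,
                           drift_rate: float = 0.1, seed: int = 0,
                           start_z: float = 30.0, jitter: float = 0.2,
                           ) -> tuple[Topology, Trajectory, dict]:
    """Membrane slab at z = 0 plus a compact pseudo-domain whose z-COM is
    flat at ``start_z`` before ``detach_frame`` and then climbs linearly at
    ``drift_rate`` A/frame, with Gaussian positional jitter throughout.
    """
    if not 0 <= detach_frame <= n_frames:
        raise ValueError("detach_frame must lie within [0, n_frames]")
    rng = np.random.default_rng(seed)
    rows = []
    base_pos = []
    # 6x6x2 slab of lipid beads spanning |z| < 8
    for ix in range(6):
        for iy in range(6):
            for iz, z in enumerate((-8.0, 8.0)):
                resid = ix * 12 + iy * 2 + iz + 1
                rows.append(_atom_row("P", "P", resid, "POPC", "L",
                                      "lipid", 30.974))
                base_pos.append((20.0 + ix * 8.0, 20.0 + iy * 8.0, z))
    n_mem = len(rows)
    # 3x3x3 cube of pseudo-CA atoms, one residue each
    for i in range(27):
        ix, r = divmod(i, 9)
        iy, iz = divmod(r, 3)
        rows.append(_atom_row("CA", "C", i + 1, "ALA", "D", "protein",
                              12.011))
        base_pos.append((35.0 + ix * 4.0, 35.0 + iy * 4.0,
                         (iz - 1) * 4.0))
    top = Topology(pd.DataFrame(rows))
    base = np.asarray(base_pos, dtype=float)

    frames = np.arange(n_frames)
    z_shift = np.where(frames < detach_frame, 0.0,
                       drift_rate * (frames - detach_frame))
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    coords[:, n_mem:, 2] += start_z + z_shift[:, None]
    coords += rng.normal(0.0, jitter, coords.shape)
    box = np.full((n_frames, 3), 400.0)
    times = np.arange(n_frames, dtype=float)
    traj = Trajectory(coords, box, times)
    truth = {
        "generator": "domain_drift",
        "seed": seed,
        "n_frames": n_frames,
        "detach_frame": detach_frame,
        "drift_rate": drift_rate,
        "start_z": start_z,
        "final_displacement": float(
            drift_rate * max(n_frames - 1 - detach_frame, 0)),
        "jitter": jitter,
        "n_membrane_atoms": n_mem,
    }
    return top, traj, truth


# ---------------------------------------------------------------------- #
# toy receptor-ligand complex for energetics oracles

def make_toy_complex(receptor_atoms: Sequence[tuple],
                     ligand_atoms: Sequence[tuple],
                     ) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Assemble a tiny receptor-ligand complex from explicit atom tuples
    ``(position, charge, lj_epsilon, lj_rmin_half, born_radius)``.

    Returns the topology (receptor = chain R, ligand = chain L), a
    single-frame trajectory, and the equivalent TSV-style parameter table.
    """
    rows = []
    pos = []
    table = []
    for chain, resname, atoms in (("R", "REC", receptor_atoms),
                                  ("L", "LIG", ligand_atoms)):
        for i, (p, q, eps, rmin, born) in enumerate(atoms):
            name = f"X{i + 1}"
            rows.append(_atom_row(name, "C", 1, resname, chain,
                                  "protein" if chain == "R" else "ligand",
                                  12.011, q, eps, rmin, born))
            pos.append(p)
            table.append(dict(resname=resname, atom_name=name, charge=q,
                              epsilon=eps, rmin_half=rmin, born_radius=born))
    top = Topology(pd.DataFrame(rows))
    coords = np.asarray(pos, dtype=float)[None, :, :]
    traj = Trajectory(coords, np.full((1, 3), _BIG_BOX), np.array([0.0]))
    return top, traj, pd.DataFrame(table)


# ---------------------------------------------------------------------- #
# random sphere clusters (surface-area oracle inputs)

def make_sphere_cluster(seed: int, max_atoms: int = 10,
                        radius_range: tuple[float, float] = (1.4, 2.0),
                        separation: tuple[float, float] = (0.88, 1.05),
                        probe: float = 1.4,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Random cluster of partially overlapping spheres for surface-area
    validation.

    Atoms are grown one at a time, each placed at a distance of
    ``separation`` times the sum of probe-augmented radii from a randomly
    chosen existing atom, with rejection so that *every* pairwise distance
    respects the lower bound.  This keeps overlaps shallow and pairwise —
    the regime of solvent-separated van der Waals contacts, where a
    truncated pairwise-overlap surface expansion is well conditioned — while
    still producing nontrivial buried area.  Returns (coords, radii).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_atoms + 1))
    radii = rng.uniform(*radius_range, n)
    aug = radii + probe
    coords = np.zeros((n, 3))
    lo, hi = separation
    for i in range(1, n):
        for _attempt in range(500):
            j = int(rng.integers(0, i))
            d = rng.uniform(lo, hi) * (aug[i] + aug[j])
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            cand = coords[j] + d * u
            dd = np.linalg.norm(coords[:i] - cand, axis=1)
            if np.all(dd >= lo * (aug[:i] + aug[i])):
                coords[i] = cand
                break
        else:
            raise RuntimeError("sphere placement failed; loosen separation")
    return coords, radii


# ---------------------------------------------------------------------- #
# helix -> extended morph (secondary-structure timeline ground truth)

def make_helix_coil_traj(n_residues: int = 12, n_frames: int = 60,
                         transition_frame: int = 30, seed: int = 0,
                         ) -> tuple[Topology, Trajectory, dict]:
    """Backbone-only chain that is an ideal alpha-helix before
    ``transition_frame`` and a fully extended strand afterwards.

    Only N, CA, C atoms are built (sufficient for phi/psi assignment).
    """
    from .ctd import build_backbone_from_dihedrals

    helix = build_backbone_from_dihedrals(
        n_residues, phi=-57.0, psi=-47.0)
    extended = build_backbone_from_dihedrals(
        n_residues, phi=-120.0, psi=120.0)
    rows = []
    for i in range(n_residues):
        for name, el, mass in (("N", "N", 14.007), ("CA", "C", 12.011),
                               ("C", "C", 12.011)):
            rows.append(_atom_row(name, el, i + 1, "ALA", "A", "protein",
                                  mass))
    top = Topology(pd.DataFrame(rows))
    coords = np.empty((n_frames, top.n_atoms, 3))
    coords[:transition_frame] = helix
    coords[transition_frame:] = extended
    rng = np.random.default_rng(seed)
    coords += rng.normal(0.0, 0.01, coords.shape)
    box = np.full((n_frames, 3), _BIG_BOX)
    traj = Trajectory(coords, box, np.arange(n_frames, dtype=float))
    truth = {
        "generator": "helix_coil",
        "seed": seed,
        "n_residues": n_residues,
        "n_frames": n_frames,
        "transition_frame": transition_frame,
    }
    return top, traj, truth


# ---------------------------------------------------------------------- #
# bundle I/O

def save_bundle(prefix: str | Path, topology: Topology,
                trajectory: Trajectory, truth: dict) -> dict[str, Path]:
    """Write ``<prefix>.pdb`` (frame 0), ``<prefix>.dcd`` (all frames) and
    ``<prefix>.json`` (ground-truth sidecar); returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": prefix.with_suffix(".pdb"),
        "dcd": prefix.with_suffix(".dcd"),
        "json": prefix.with_suffix(".json"),
    }
    write_structure(topology, trajectory.coordinates[0], paths["pdb"],
                    box=trajectory.box[0])
    write_trajectory(topology, trajectory, paths["dcd"])
    with open(paths["json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
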