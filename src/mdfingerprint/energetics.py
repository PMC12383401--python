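"""MM/GBSA binding energetics and hydrogen-bond occupancy.

Binding free energies follow the single-trajectory end-state protocol:
for each snapshot, ``dG_bind = dE_MM + dG_solv`` where every component is
the complex value minus the isolated receptor and ligand values computed at
identical internal geometry (so the internal/bonded term cancels exactly).

* gas-phase electrostatics: pairwise Coulomb, k_e = 332.0636 kcal*A/(mol*e^2),
  no cutoff;
* van der Waals: 12-6 Lennard-Jones with Lorentz-Berthelot combining;
* polar solvation: Still-style generalized Born with OBC-II effective radii
  and Debye-Hueckel salt screening (defaults: eps_in 1.0, eps_out 80.0,
  400 mM 1:1 electrolyte at 298 K);
* nonpolar solvation: gamma * SASA with the LCPO analytic surface area,
  gamma = 0.0072 kcal/(mol*A^2), probe 1.4 A.

Entropy terms are omitted by construction.  Ensemble estimates average the
decomposition over snapshots picked from the tail of the trajectory
(default: final 100 ns at 2 ns intervals) and report the standard error of
the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const

from .core import (Selection, Topology, Trajectory, min_image_displacement)

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyDecomposition",
    "GBSAOptions",
    "HBondCriterion",
    "coulomb_energy",
    "lj_energy",
    "born_radii",
    "gb_energy",
    "debye_kappa",
    "lcpo_sasa",
    "LCPO_PARAMS",
    "mmgbsa_snapshot",
    "mmgbsa_ensemble",
    "pick_frames",
    "hbond_occupancy",
    "delta_occupancy",
]

#: Coulomb constant in kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0636


# ---------------------------------------------------------------------- #
# gas-phase terms

def _pair_distances(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(coords)
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    return iu, d


def coulomb_energy(coords: np.ndarray, charges: np.ndarray,
                   interior_dielectric: float = 1.0) -> float:
    """Total pairwise Coulomb energy, kcal/mol, no cutoff."""
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    if len(coords) < 2:
        return 0.0
    iu, d = _pair_distances(coords)
    charged = (q[iu[0]] != 0) & (q[iu[1]] != 0)
    if np.any(d[charged] < 1e-8):
        raise ValueError("coincident charged atoms")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(d > 0, q[iu[0]] * q[iu[1]] / d, 0.0)
    return float(COULOMB_CONSTANT / interior_dielectric * e.sum())


def lj_energy(coords: np.ndarray, epsilon: np.ndarray,
              rmin_half: np.ndarray) -> float:
    """12-6 Lennard-Jones energy with Lorentz-Berthelot combining:
    eps_ij = sqrt(eps_i eps_j), rmin_ij = rmin_half_i + rmin_half_j."""
    coords = np.asarray(coords, dtype=float)
    eps = np.asarray(epsilon, dtype=float)
    rh = np.asarray(rmin_half, dtype=float)
    if len(coords) < 2:
        return 0.0
    iu, d = _pair_distances(coords)
    eij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    active = eij > 0
    if np.any(d[active] < 1e-8):
        raise ValueError("coincident interacting atoms")
    rmin = rh[iu[0]] + rh[iu[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(d > 0, (rmin / d) ** 6, 0.0)
    return float(np.sum(eij * (sr6 ** 2 - 2.0 * sr6)))


# ---------------------------------------------------------------------- #
# generalized Born

_OBC2_ALPHA, _OBC2_BETA, _OBC2_GAMMA = 1.0, 0.8, 4.85
_GB_OFFSET = 0.09  # A, intrinsic-to-reduced radius offset
_DEFAULT_SCREEN = 0.8


def _hct_integral(r: np.ndarray, rho_i: float | np.ndarray,
                  sr_j: np.ndarray) -> np.ndarray:
    """Pairwise descreening integral of a scaled neighbor sphere (radius
    ``sr_j`` at distance ``r``) over the exterior of the self sphere
    ``rho_i``: (1/4pi) * Int_{V_j \\ V_i} dV / d^4."""
    r = np.asarray(r, dtype=float)
    sr = np.asarray(sr_j, dtype=float)
    rho = np.broadcast_to(np.asarray(rho_i, dtype=float), r.shape)
    out = np.zeros_like(r)
    # neighbor sphere entirely buried inside the self sphere: no descreening
    mask = r + sr > rho
    if not mask.any():
        return out
    r_, sr_, rho_ = r[mask], sr[mask], rho[mask]
    u = r_ + sr_
    low = np.maximum(np.abs(r_ - sr_), rho_)
    i = 0.5 * (1.0 / low - 1.0 / u
               + 0.25 * (r_ - sr_ ** 2 / r_) * (1.0 / u ** 2
                                                - 1.0 / low ** 2)
               + 0.5 / r_ * np.log(low / u))
    # self sphere engulfed by the neighbor sphere
    inside = rho_ < sr_ - r_
    i = i + np.where(inside, 1.0 / rho_ - 1.0 / low, 0.0)
    out[mask] = i
    return out


def born_radii(coords: np.ndarray, intrinsic_radii: np.ndarray,
               screen: np.ndarray | float = _DEFAULT_SCREEN,
               offset: float = _GB_OFFSET) -> np.ndarray:
    """OBC-II effective Born radii from pairwise descreening.

    An isolated atom's effective radius is its intrinsic radius minus the
    offset (0.09 A); burial by neighbors only ever increases it.
    """
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(intrinsic_radii, dtype=float)
    if (rho <= 0).any():
        raise ValueError("intrinsic radii must be positive")
    n = len(coords)
    s = np.broadcast_to(np.asarray(screen, dtype=float), (n,))
    rho_red = rho - offset
    psi_i = np.zeros(n)
    for i in range(n):
        others = np.arange(n) != i
        if not others.any():
            continue
        r = np.linalg.norm(coords[others] - coords[i], axis=1)
        integral = _hct_integral(r, rho_red[i], s[others] * rho_red[others])
        psi_i[i] = integral.sum()
    psi = rho_red * psi_i
    tanh_arg = _OBC2_ALPHA * psi - _OBC2_BETA * psi ** 2 \
        + _OBC2_GAMMA * psi ** 3
    inv_reff = 1.0 / rho_red - np.tanh(tanh_arg) / rho
    if (inv_reff <= 0).any():
        # extreme burial: cap at a large but finite effective radius
        inv_reff = np.maximum(inv_reff, 1e-4)
    return 1.0 / inv_reff


def debye_kappa(salt_molar: float, eps_out: float = 80.0,
                temperature: float = 298.15) -> float:
    """Inverse Debye screening length (1/A) for a 1:1 electrolyte."""
    if salt_molar < 0:
        raise ValueError("salt concentration must be non-negative")
    if salt_molar == 0:
        return 0.0
    ionic_m3 = salt_molar * 1000.0 * _const.N_A  # ions/m^3 per species
    kappa_sq = (2.0 * ionic_m3 * _const.e ** 2
                / (_const.epsilon_0 * eps_out * _const.k * temperature))
    return float(np.sqrt(kappa_sq) * 1e-10)


def gb_energy(coords: np.ndarray, charges: np.ndarray,
              effective_radii: np.ndarray, eps_in: float = 1.0,
              eps_out: float = 80.0, salt_molar: float = 0.4,
              temperature: float = 298.15) -> float:
    """Still-style generalized Born polar solvation energy, kcal/mol.

    dG = -k_e/2 * sum_ij (1/eps_in - exp(-kappa f_ij)/eps_out) q_i q_j / f_ij
    with f_ij = sqrt(r_ij^2 + R_i R_j exp(-r_ij^2 / (4 R_i R_j))); the
    double sum runs over all i, j including the self terms (i = j, f = R_i).
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    reff = np.asarray(effective_radii, dtype=float)
    if (reff <= 0).any():
        raise ValueError("effective radii must be positive")
    kappa = debye_kappa(salt_molar, eps_out, temperature)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff ** 2, axis=-1)
    rirj = reff[:, None] * reff[None, :]
    f = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    prefac = 1.0 / eps_in - np.exp(-kappa * f) / eps_out
    qq = q[:, None] * q[None, :]
    return float(-COULOMB_CONSTANT / 2.0 * np.sum(prefac * qq / f))


# ---------------------------------------------------------------------- #
# LCPO solvent-accessible surface area

#: LCPO coefficients (P1..P4) keyed by atom type.  The named entries are the
#: published fit for common biomolecular heavy atoms, keyed as
#: ``<element>_<hybridisation>_<n bonded heavy atoms>``; ``sphere`` is the
#: exact truncated inclusion-exclusion limit for free (non-bonded) spheres
#: and is the default for synthetic atoms without covalent context.
LCPO_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "sphere": (1.0, -1.0, 0.0, 0.0),
    "C_sp3_1": (0.77887, -0.28063, -0.0012968, 0.00039328),
    "C_sp3_2": (0.56482, -0.19608, -0.0010219, 0.0002658),
    "C_sp3_3": (0.23348, -0.072627, -0.00020079, 0.00007967),
    "C_sp3_4": (0.0, 0.0, 0.0, 0.0),
    "O_sp3_1": (0.77914, -0.25262, -0.0016056, 0.00035071),
    "O_sp3_2": (0.49392, -0.16038, -0.00015512, 0.00016453),
    "O_sp2_1": (0.68563, -0.1868, -0.00135573, 0.00023743),
    "O_carboxylate": (0.88857, -0.33421, -0.0018683, 0.00049372),
}


def lcpo_sasa(coords: np.ndarray, radii: np.ndarray,
              param_keys: list[str] | None = None,
              probe: float = 1.4) -> tuple[np.ndarray, float]:
    """Analytic solvent-accessible surface area by linear combination of
    pairwise overlaps.

    ``radii`` are heavy-atom radii (hydrogens must be excluded upstream);
    they are augmented by the probe radius.  ``param_keys`` selects the
    per-atom coefficient set from :data:`LCPO_PARAMS` (default: the free
    ``sphere`` set for every atom).  Negative per-atom areas are clamped to
    zero.  Returns (per-atom areas, total), in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    rr = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    if param_keys is None:
        param_keys = ["sphere"] * n
    params = np.empty((n, 4))
    for i, key in enumerate(param_keys):
        if key not in LCPO_PARAMS:
            raise KeyError(f"no LCPO parameters for atom type {key!r}")
        params[i] = LCPO_PARAMS[key]

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))
    overlap = (dist < rr[:, None] + rr[None, :]) \
        & ~np.eye(n, dtype=bool)

    def a_overlap(i: int, j: int) -> float:
        # area of sphere i buried by sphere j (spherical cap on i)
        d = dist[i, j]
        return 2.0 * np.pi * rr[i] * (
            rr[i] - d / 2.0 - (rr[i] ** 2 - rr[j] ** 2) / (2.0 * d))

    per_atom = np.empty(n)
    for i in range(n):
        s1 = 4.0 * np.pi * rr[i] ** 2
        nbrs = np.flatnonzero(overlap[i])
        sum_aij = sum(a_overlap(i, j) for j in nbrs)
        sum_ajk = 0.0
        sum_aij_ajk = 0.0
        for j in nbrs:
            ajk_j = 0.0
            for k in nbrs:
                if k != j and overlap[j, k]:
                    ajk_j += a_overlap(j, k)
            sum_ajk += ajk_j
            sum_aij_ajk += a_overlap(i, j) * ajk_j
        p1, p2, p3, p4 = params[i]
        area = p1 * s1 + p2 * sum_aij + p3 * sum_ajk + p4 * sum_aij_ajk
        per_atom[i] = max(area, 0.0)
    return per_atom, float(per_atom.sum())


# ---------------------------------------------------------------------- #
# MM-GBSA assembly

@dataclass
class GBSAOptions:
    """Tunable constants of the MM/GBSA protocol."""

    eps_in: float = 1.0
    eps_out: float = 80.0
    salt_molar: float = 0.4
    gamma: float = 0.0072          # kcal/(mol*A^2), nonpolar surface tension
    probe: float = 1.4             # A
    temperature: float = 298.15    # K, enters only the Debye length
    gb_offset: float = 0.09        # A
    sasa_param_key: str = "sphere"


@dataclass
class EnergyDecomposition:
    """MM-GBSA component breakdown, kcal/mol.

    ``g_total`` always equals the sum of the five components; for ensembles
    the components are snapshot means, ``sem`` is the standard error of the
    total and ``component_sem`` of each component.
    """

    e_internal: float
    e_electrostatic: float
    e_vdw: float
    g_polar_solv: float
    g_nonpolar_solv: float
    g_total: float
    n_snapshots: int = 1
    sem: float | None = None
    component_sem: dict = field(default_factory=dict)

    def components(self) -> dict[str, float]:
        return {
            "e_internal": self.e_internal,
            "e_electrostatic": self.e_electrostatic,
            "e_vdw": self.e_vdw,
            "g_polar_solv": self.g_polar_solv,
            "g_nonpolar_solv": self.g_nonpolar_solv,
        }

    def check_identity(self, atol: float = 1e-6) -> None:
        total = sum(self.components().values())
        if abs(total - self.g_total) > atol:
            raise AssertionError(
                f"decomposition identity violated: {total} != {self.g_total}")


def _species_energy(coords, charges, eps, rmin, intrinsic, screen,
                    heavy_mask, opt: GBSAOptions) -> dict[str, float]:
    e_coul = coulomb_energy(coords, charges, opt.eps_in)
    e_vdw = lj_energy(coords, eps, rmin)
    reff = born_radii(coords, intrinsic, screen, offset=opt.gb_offset)
    g_pol = gb_energy(coords, charges, reff, opt.eps_in, opt.eps_out,
                      opt.salt_molar, opt.temperature)
    _, sasa = lcpo_sasa(coords[heavy_mask], intrinsic[heavy_mask],
                        [opt.sasa_param_key] * int(heavy_mask.sum()),
                        probe=opt.probe)
    return dict(coul=e_coul, vdw=e_vdw, gb=g_pol,
                nonpolar=opt.gamma * sasa)


def mmgbsa_snapshot(topology: Topology, frame: np.ndarray,
                    receptor_selection: Selection,
                    ligand_selection: Selection,
                    options: GBSAOptions | None = None,
                    ) -> EnergyDecomposition:
    """Single-snapshot binding decomposition, complex minus parts.

    The receptor and ligand selections must be disjoint; the internal
    (bonded) term is identically zero under the single-trajectory protocol
    because the isolated species keep the complex geometry.
    """
    opt = options or GBSAOptions()
    r_idx = receptor_selection.atom_indices
    l_idx = ligand_selection.atom_indices
    if len(r_idx) == 0 or len(l_idx) == 0:
        raise ValueError("receptor and ligand selections must be non-empty")
    if np.intersect1d(r_idx, l_idx).size:
        raise ValueError("receptor and ligand selections overlap")
    a = topology.atoms
    for col in ("charge", "lj_epsilon", "lj_rmin_half", "born_radius"):
        vals = a[col].to_numpy(dtype=float)
        if np.isnan(vals[np.concatenate([r_idx, l_idx])]).any():
            raise ValueError(f"atoms missing {col}; apply a parameter table")
    q = a["charge"].to_numpy(dtype=float)
    eps = a["lj_epsilon"].to_numpy(dtype=float)
    rmin = a["lj_rmin_half"].to_numpy(dtype=float)
    rho = a["born_radius"].to_numpy(dtype=float)
    if "gb_screen" in a.columns:
        screen = a["gb_screen"].to_numpy(dtype=float)
        screen = np.where(np.isnan(screen), _DEFAULT_SCREEN, screen)
    else:
        screen = np.full(len(a), _DEFAULT_SCREEN)
    heavy = (a["element"] != "H").to_numpy()

    frame = np.asarray(frame, dtype=float)
    c_idx = np.concatenate([r_idx, l_idx])
    parts = {}
    for tag, idx in (("complex", c_idx), ("receptor", r_idx),
                     ("ligand", l_idx)):
        parts[tag] = _species_energy(frame[idx], q[idx], eps[idx],
                                     rmin[idx], rho[idx], screen[idx],
                                     heavy[idx], opt)

    def delta(key: str) -> float:
        return parts["complex"][key] - parts["receptor"][key] \
            - parts["ligand"][key]

    e_elec = delta("coul")
    e_vdw = delta("vdw")
    g_pol = delta("gb")
    g_np = delta("nonpolar")
    total = e_elec + e_vdw + g_pol + g_np
    return EnergyDecomposition(
        e_internal=0.0, e_electrostatic=e_elec, e_vdw=e_vdw,
        g_polar_solv=g_pol, g_nonpolar_solv=g_np, g_total=total,
        n_snapshots=1)


def pick_frames(frame_times: np.ndarray, last_ns: float = 100.0,
                interval_ns: float = 2.0) -> np.ndarray:
    """Indices of snapshots spanning the final ``last_ns`` of the
    trajectory at ``interval_ns`` spacing (nearest frame per target time).

    On a 500 ns trajectory with last_ns=100 and interval_ns=2 this yields
    exactly 50 snapshots.
    """
    times = np.asarray(frame_times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty trajectory")
    t_end = times[-1]
    targets = np.arange(t_end - last_ns + interval_ns, t_end + 1e-9,
                        interval_ns)
    idx = np.unique([int(np.argmin(np.abs(times - t))) for t in targets])
    return idx


def mmgbsa_ensemble(topology: Topology, traj: Trajectory,
                    receptor_selection: Selection,
                    ligand_selection: Selection,
                    frame_indices: np.ndarray | None = None,
                    last_ns: float = 100.0, interval_ns: float = 2.0,
                    options: GBSAOptions | None = None,
                    ) -> EnergyDecomposition:
    """Snapshot-averaged binding decomposition with standard errors.

    Snapshots default to the trailing-window picker (final ``last_ns`` at
    ``interval_ns`` spacing); at least two snapshots are required.
    """
    if frame_indices is None:
        frame_indices = pick_frames(traj.frame_times, last_ns, interval_ns)
    frame_indices = np.asarray(frame_indices, dtype=int)
    if len(frame_indices) < 2:
        raise ValueError("ensemble MM-GBSA needs at least 2 snapshots")
    rows = []
    for f in frame_indices:
        snap = mmgbsa_snapshot(topology, traj.coordinates[f],
                               receptor_selection, ligand_selection, options)
        rows.append({**snap.components(), "g_total": snap.g_total})
    df = pd.DataFrame(rows)
    n = len(df)
    mean = df.mean()
    sem = df.std(ddof=1) / np.sqrt(n)
    return EnergyDecomposition(
        e_internal=float(mean["e_internal"]),
        e_electrostatic=float(mean["e_electrostatic"]),
        e_vdw=float(mean["e_vdw"]),
        g_polar_solv=float(mean["g_polar_solv"]),
        g_nonpolar_solv=float(mean["g_nonpolar_solv"]),
        g_total=float(mean["g_total"]),
        n_snapshots=n,
        sem=float(sem["g_total"]),
        component_sem={k: float(sem[k]) for k in snap.components()},
    )


# ---------------------------------------------------------------------- #
# hydrogen-bond occupancy

@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition: donor-acceptor distance at most
    ``max_da_distance`` and donor-hydrogen-acceptor angle at least
    ``min_dha_angle``."""

    max_da_distance: float = 3.5  # A
    min_dha_angle: float = 150.0  # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


def _attached_hydrogens(topology: Topology, frame0: np.ndarray,
                        donor_idx: int, max_bond: float = 1.3) -> np.ndarray:
    """Hydrogens of the donor's residue within covalent range in frame 0."""
    a = topology.atoms
    chain = a.at[donor_idx, "chain"]
    resid = a.at[donor_idx, "resid"]
    cand = np.flatnonzero((a["element"] == "H").to_numpy()
                          & (a["chain"] == chain).to_numpy()
                          & (a["resid"] == resid).to_numpy())
    if len(cand) == 0:
        return cand
    d = np.linalg.norm(frame0[cand] - frame0[donor_idx], axis=1)
    return cand[d <= max_bond]


def hbond_occupancy(topology: Topology, traj: Trajectory,
                    criterion: HBondCriterion | None = None,
                    donors: Selection | None = None,
                    acceptors: Selection | None = None,
                    min_occupancy_pct: float = 0.0) -> pd.DataFrame:
    """Fraction of frames each donor-acceptor pair is hydrogen bonded.

    Donors default to N/O atoms with an attached hydrogen; acceptors to N/O
    atoms.  A frame counts when the minimum-image D-A distance and the
    D-H-A angle (any attached hydrogen) satisfy the criterion.  Donors
    without an attached hydrogen are skipped with a warning.  Returns an
    occupancy table with one row per pair at or above
    ``min_occupancy_pct``.
    """
    crit = criterion or HBondCriterion()
    a = topology.atoms
    polar = a["element"].isin(["N", "O"]).to_numpy()
    explicit_donors = donors is not None
    if donors is None:
        donors = Selection(np.flatnonzero(polar), label="polar")
    if acceptors is None:
        acceptors = Selection(np.flatnonzero(polar), label="polar")
    frame0 = traj.coordinates[0]
    rows = []
    cos_min = np.cos(np.deg2rad(crit.min_dha_angle))
    for d_idx in donors.atom_indices:
        hyds = _attached_hydrogens(topology, frame0, int(d_idx))
        if len(hyds) == 0:
            if not explicit_donors:
                continue  # auto-detected polar atom; simply not a donor
            warnings.warn(
                f"donor atom {a.at[int(d_idx), 'name']} "
                f"({a.at[int(d_idx), 'chain']}{a.at[int(d_idx), 'resid']}) "
                "has no attached hydrogen; skipped", stacklevel=2)
            continue
        for a_idx in acceptors.atom_indices:
            if a_idx == d_idx:
                continue
            same_res = (a.at[int(a_idx), "chain"] == a.at[int(d_idx), "chain"]
                        and a.at[int(a_idx), "resid"]
                        == a.at[int(d_idx), "resid"])
            if same_res:
                continue
            da = min_image_displacement(traj.coordinates[:, a_idx],
                                        traj.coordinates[:, d_idx],
                                        traj.box)
            dist_ok = np.linalg.norm(da, axis=1) <= crit.max_da_distance
            ang_ok = np.zeros(traj.n_frames, dtype=bool)
            for h_idx in hyds:
                hd = min_image_displacement(traj.coordinates[:, d_idx],
                                            traj.coordinates[:, h_idx],
                                            traj.box)
                ha = min_image_displacement(traj.coordinates[:, a_idx],
                                            traj.coordinates[:, h_idx],
                                            traj.box)
                num = np.sum(hd * ha, axis=1)
                den = (np.linalg.norm(hd, axis=1)
                       * np.linalg.norm(ha, axis=1))
                cosang = np.where(den > 0, num / den, 1.0)
                # angle >= min  <=>  cos(angle) <= cos(min)
                ang_ok |= cosang <= cos_min
            occ = 100.0 * float(np.mean(dist_ok & ang_ok))
            if occ >= min_occupancy_pct:
                rows.append(dict(
                    donor_chain=a.at[int(d_idx), "chain"],
                    donor_resid=int(a.at[int(d_idx), "resid"]),
                    donor_atom=a.at[int(d_idx), "name"],
                    acceptor_chain=a.at[int(a_idx), "chain"],
                    acceptor_resid=int(a.at[int(a_idx), "resid"]),
                    acceptor_atom=a.at[int(a_idx), "name"],
                    occupancy_pct=occ,
                    n_frames=traj.n_frames,
                ))
    return pd.DataFrame(rows, columns=[
        "donor_chain", "donor_resid", "donor_atom", "acceptor_chain",
        "acceptor_resid", "acceptor_atom", "occupancy_pct", "n_frames"])


_PAIR_KEY = ["donor_chain", "donor_resid", "donor_atom",
             "acceptor_chain", "acceptor_resid", "acceptor_atom"]


def delta_occupancy(cold: pd.DataFrame, hot: pd.DataFrame) -> pd.DataFrame:
    """Per-pair cold-minus-hot occupancy change (sign convention
    273 K - 323 K)."""
    ck = cold.set_index(_PAIR_KEY)
    hk = hot.set_index(_PAIR_KEY)
    if set(ck.index) != set(hk.index):
        diff = sorted(set(ck.index).symmetric_difference(hk.index))
        raise ValueError(f"pair lists differ: {diff[:5]}"
                         + ("..." if len(diff) > 5 else ""))
    out = ck[["occupancy_pct"]].rename(
        columns={"occupancy_pct": "occupancy_cold_pct"})
    out["occupancy_hot_pct"] = hk["occupancy_pct"]
    out["delta_pct"] = out["occupancy_cold_pct"] - out["occupancy_hot_pct"]
    return out.reset_index()
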