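"""Protein-lipid proximity, contact occupancy, and acyl-chain order.

Two distinct per-residue contact statistics mirror the two measurement
conventions common in membrane-protein work: the *minimum distance* profile
uses only each residue's C-alpha against any lipid atom (time-averaged),
while the *occupancy* profile counts a frame as a contact when **any** atom
of the residue lies within the cutoff (default 5.0 A) of any lipid atom.
Both use minimum-image distances.

The deuterium order parameter S_CD = <(3 cos^2 theta - 1)/2> measures acyl
tail alignment with the bilayer normal (+1 fully aligned, 0 isotropic, -0.5
in-plane).  The default per-carbon convention takes theta as the angle
between the C_{k-1} -> C_{k+1} vector and the normal (the united-atom
surrogate for the C-D bond direction rotated by 90 degrees is folded into
cos^2, which is insensitive to sign); a whole-chain-axis mode averaging all
C-C bond vectors per chain is also available.  Leaflets are pooled: cos^2
is invariant under z reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import re

import numpy as np
import pandas as pd

from .core import (PerResidueProfile, Selection, Topology, Trajectory,
                   min_image_displacement)

__all__ = [
    "ScdProfile",
    "residue_lipid_min_distance",
    "lipid_occupancy",
    "delta_occupancy_profile",
    "lipid_chains",
    "scd_profile",
    "delta_scd",
]

#: atom-name regexes selecting the ordered acyl carbons per chain
#: (CHARMM POPC convention: sn-1 = C3x, sn-2 = C2x)
CHAIN_NAME_RULES: dict[str, str] = {
    "sn1": r"^C3(\d+)$",
    "sn2": r"^C2(\d+)$",
}


@dataclass
class ScdProfile:
    """Per-carbon order parameter along one acyl chain."""

    chain_id: str  # "sn1" or "sn2"
    entries: pd.DataFrame  # columns: carbon, s_cd

    def __post_init__(self) -> None:
        if self.chain_id not in ("sn1", "sn2"):
            raise ValueError("chain_id must be 'sn1' or 'sn2'")
        v = self.entries["s_cd"].to_numpy(dtype=float)
        if ((v < -0.5 - 1e-9) | (v > 1.0 + 1e-9)).any():
            raise ValueError("s_cd out of the [-0.5, 1] range")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.entries["carbon"], self.entries["s_cd"]))


# ---------------------------------------------------------------------- #
# residue-lipid contacts

def _per_frame_min_dist(traj: Trajectory, point_idx: np.ndarray,
                        lipid_idx: np.ndarray) -> np.ndarray:
    """(n_frames, n_points) minimum-image distance from each point atom to
    the nearest lipid atom, per frame."""
    n_frames = traj.n_frames
    out = np.empty((n_frames, len(point_idx)))
    for f in range(n_frames):
        box = traj.box[f]
        pts = traj.coordinates[f, point_idx]
        lip = traj.coordinates[f, lipid_idx]
        d = min_image_displacement(pts[:, None, :], lip[None, :, :], box)
        out[f] = np.sqrt(np.sum(d ** 2, axis=-1)).min(axis=1)
    return out


def residue_lipid_min_distance(topology: Topology, traj: Trajectory,
                               protein_residues: Selection,
                               lipid_atoms: Selection) -> PerResidueProfile:
    """Time-averaged minimum distance from each residue's C-alpha to any
    lipid atom.  Residues without a C-alpha are skipped with a warning."""
    if len(protein_residues) == 0 or len(lipid_atoms) == 0:
        raise ValueError("selections must be non-empty")
    a = topology.atoms
    sel = set(protein_residues.atom_indices.tolist())
    ca_idx = []
    rids = []
    for rid, idx in topology.residues():
        if not sel.intersection(idx.tolist()):
            continue
        ca = [i for i in idx if a.at[int(i), "name"] == "CA"]
        if not ca:
            warnings.warn(f"residue {rid} has no CA atom; skipped",
                          stacklevel=2)
            continue
        ca_idx.append(ca[0])
        rids.append(rid)
    if not ca_idx:
        raise ValueError("no residues with C-alpha atoms in selection")
    dmin = _per_frame_min_dist(traj, np.asarray(ca_idx),
                               lipid_atoms.atom_indices)
    mean_d = dmin.mean(axis=0)
    rows = [dict(chain=rid[0], resid=rid[1], value=float(v))
            for rid, v in zip(rids, mean_d)]
    return PerResidueProfile(pd.DataFrame(rows), "min_distance",
                             metadata=dict(n_frames=traj.n_frames))


def lipid_occupancy(topology: Topology, traj: Trajectory,
                    protein_residues: Selection, lipid_atoms: Selection,
                    cutoff: float = 5.0) -> PerResidueProfile:
    """Percentage of frames each residue contacts a lipid.

    A frame counts when any atom of the residue is within ``cutoff`` of any
    lipid atom (minimum image)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(protein_residues) == 0 or len(lipid_atoms) == 0:
        raise ValueError("selections must be non-empty")
    sel = set(protein_residues.atom_indices.tolist())
    rows = []
    lip = lipid_atoms.atom_indices
    for rid, idx in topology.residues():
        res_atoms = np.asarray([i for i in idx if int(i) in sel])
        if len(res_atoms) == 0:
            continue
        dmin = _per_frame_min_dist(traj, res_atoms, lip)
        contact = (dmin <= cutoff).any(axis=1)
        rows.append(dict(chain=rid[0], resid=rid[1],
                         value=100.0 * float(contact.mean())))
    return PerResidueProfile(pd.DataFrame(rows), "occupancy_pct",
                             metadata=dict(cutoff=cutoff,
                                           n_frames=traj.n_frames))


def delta_occupancy_profile(cold: PerResidueProfile,
                            hot: PerResidueProfile) -> PerResidueProfile:
    """Cold-minus-hot lipid occupancy change per residue (273 K - 323 K)."""
    for p in (cold, hot):
        if p.value_kind != "occupancy_pct":
            raise ValueError("inputs must be occupancy profiles")
    c = cold.as_dict()
    h = hot.as_dict()
    if set(c) != set(h):
        diff = sorted(set(c).symmetric_difference(h))
        raise ValueError(f"residue sets differ: {diff[:10]}")
    rows = [dict(chain=rid[0], resid=rid[1], value=c[rid] - h[rid])
            for rid in cold.residue_ids()]
    return PerResidueProfile(pd.DataFrame(rows), "delta_occupancy",
                             metadata=dict(sign="cold-minus-hot"))


# ---------------------------------------------------------------------- #
# acyl-chain order parameters

def lipid_chains(topology: Topology, chain_id: str,
                 name_rules: dict[str, str] | None = None,
                 ) -> list[np.ndarray]:
    """Per-lipid ordered carbon index lists for one acyl chain.

    Membership is decided by atom-name pattern (default CHARMM POPC naming,
    sn-1 = ``C3<k>``, sn-2 = ``C2<k>``), ordered by the carbon number."""
    rules = name_rules or CHAIN_NAME_RULES
    if chain_id not in rules:
        raise ValueError(f"unknown chain id {chain_id!r}")
    pat = re.compile(rules[chain_id])
    a = topology.atoms
    out = []
    for rid, idx in topology.residues():
        if a.at[int(idx[0]), "segment"] != "lipid":
            continue
        matched = []
        for i in idx:
            m = pat.match(a.at[int(i), "name"])
            if m:
                matched.append((int(m.group(1)), int(i)))
        if matched:
            matched.sort()
            out.append(np.asarray([i for _, i in matched]))
    return out


def _lipid_in_shell(traj: Trajectory, lipid_atom_idx: np.ndarray,
                    protein_idx: np.ndarray, shell: float) -> np.ndarray:
    """(n_frames,) bool: any lipid atom within ``shell`` of any protein
    atom."""
    dmin = _per_frame_min_dist(traj, lipid_atom_idx, protein_idx)
    return (dmin <= shell).any(axis=1)


def scd_profile(topology: Topology, traj: Trajectory, chain_id: str,
                normal_axis: int = 2, mode: str = "per_carbon",
                protein_selection: Selection | None = None,
                shell: float = 6.0,
                name_rules: dict[str, str] | None = None) -> ScdProfile:
    """Order parameter profile S_CD(k) along one acyl chain.

    ``mode='per_carbon'`` (default) uses the C_{k-1} -> C_{k+1} vector for
    carbon k (reported for k = 2..n-1); ``mode='chain_axis'`` assigns every
    carbon the order parameter of the mean C-C bond vector of its chain.
    If ``protein_selection`` is given, a lipid contributes in a frame only
    when one of its chain atoms lies within ``shell`` (A) of the protein.
    Averages pool both leaflets, all lipids and all frames.
    """
    chains = lipid_chains(topology, chain_id, name_rules)
    if not chains:
        raise ValueError(f"no lipids with {chain_id} chain atoms found")
    n_carbons = len(chains[0])
    if n_carbons < 3:
        raise ValueError("chains must have at least 3 carbons")
    if any(len(c) != n_carbons for c in chains):
        raise ValueError("inconsistent chain lengths across lipids")
    axis = np.zeros(3)
    axis[normal_axis] = 1.0

    coords = traj.coordinates
    # accumulate cos^2 theta sums per carbon position
    if mode == "per_carbon":
        carbons = np.arange(2, n_carbons)  # report k = 2..n-1 (1-based)
        sums = np.zeros(len(carbons))
        count = 0.0
    elif mode == "chain_axis":
        carbons = np.arange(1, n_carbons + 1)
        sums = 0.0
        count = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for ch in chains:
        pos = coords[:, ch, :]  # (frames, n_carbons, 3)
        if protein_selection is not None:
            inside = _lipid_in_shell(traj, ch,
                                     protein_selection.atom_indices, shell)
            if not inside.any():
                continue
            pos = pos[inside]
        if mode == "per_carbon":
            vec = pos[:, 2:, :] - pos[:, :-2, :]  # C_{k-1} -> C_{k+1}
            norm = np.linalg.norm(vec, axis=-1)
            cos2 = (vec @ axis / norm) ** 2
            sums += cos2.sum(axis=0)
            count += pos.shape[0]
        else:
            bonds = pos[:, 1:, :] - pos[:, :-1, :]
            mean_axis = bonds.mean(axis=1)
            norm = np.linalg.norm(mean_axis, axis=-1)
            cos2 = (mean_axis @ axis / norm) ** 2
            sums += cos2.sum()
            count += pos.shape[0]
    if count == 0:
        raise ValueError("no lipid-frame samples (shell filter excluded "
                         "every lipid)")
    if mode == "per_carbon":
        scd = (3.0 * sums / count - 1.0) / 2.0
        entries = pd.DataFrame({"carbon": carbons, "s_cd": scd})
    else:
        scd = float((3.0 * sums / count - 1.0) / 2.0)
        entries = pd.DataFrame({"carbon": carbons,
                                "s_cd": np.full(n_carbons, scd)})
    return ScdProfile(chain_id=chain_id, entries=entries)


def delta_scd(hot: ScdProfile, cold: ScdProfile) -> pd.DataFrame:
    """Hot-minus-cold order change per carbon (323 K - 273 K: negative
    values mean order lost on heating)."""
    if hot.chain_id != cold.chain_id:
        raise ValueError("profiles are for different chains")
    h = hot.as_dict()
    c = cold.as_dict()
    if set(h) != set(c):
        raise ValueError(f"carbon indices differ: "
                         f"{sorted(set(h).symmetric_difference(c))}")
    carbons = sorted(h)
    return pd.DataFrame({
        "carbon": carbons,
        "s_cd_hot": [h[k] for k in carbons],
        "s_cd_cold": [c[k] for k in carbons],
        "delta_s_cd": [h[k] - c[k] for k in carbons],
    })
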