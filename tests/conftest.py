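"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own code paths: surface
areas come from Fibonacci-lattice point sampling, descreening integrals
from scipy quadrature, and correlation matrices from explicit double loops.
"""

from __future__ import annotations

import numpy as np
import pytest


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 6000) -> float:
    """Numerical solvent-accessible surface area by point sampling on a
    Fibonacci sphere lattice (independent of any analytic SASA)."""
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    k = np.arange(n_points)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    phi = 2.0 * np.pi * k / golden
    unit = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    aug = np.asarray(radii, dtype=float) + probe
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + aug[i] * unit
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            buried |= np.linalg.norm(pts - coords[j], axis=1) < aug[j]
        total += 4.0 * np.pi * aug[i] ** 2 * (1.0 - buried.mean())
    return total


def descreening_integral_quadrature(r: float, rho_i: float,
                                    sr_j: float) -> float:
    """(1/4pi) * integral of d^-4 over the scaled neighbor sphere minus the
    self sphere, by 1D quadrature over the polar angle.

    For each angle theta from the axis joining the atoms, the radial
    integral of s^-2 has a closed form; only the angular integral is
    numerical.
    """
    from scipy.integrate import quad

    def integrand(theta):
        # points at distance s from atom i, angle theta from the i->j axis,
        # are inside the neighbor sphere iff s^2 - 2 s r cos(theta) + r^2
        # <= sr_j^2
        ct = np.cos(theta)
        disc = (r * ct) ** 2 - (r ** 2 - sr_j ** 2)
        if disc <= 0:
            return 0.0
        s_lo = r * ct - np.sqrt(disc)
        s_hi = r * ct + np.sqrt(disc)
        s_lo = max(s_lo, rho_i)
        if s_hi <= s_lo:
            return 0.0
        return 0.5 * np.sin(theta) * (1.0 / s_lo - 1.0 / s_hi)

    val, _err = quad(integrand, 0.0, np.pi, limit=400, epsabs=1e-12,
                     epsrel=1e-12)
    return val


@pytest.fixture(scope="session")
def gaussian_block_system():
    """20-residue Gaussian network with planted block correlations
    {1.0, 0.7, 0.0, -1.0} at 5000 frames, plus the planted matrix."""
    from mdfingerprint import synth

    n = 20
    corr = np.eye(n)
    corr[2, 3] = corr[3, 2] = 1.0
    corr[5, 8] = corr[8, 5] = 0.7
    corr[12, 13] = corr[13, 12] = -1.0
    cov = synth.covariance_from_residue_correlation(corr, sigma=1.0)
    top, traj, truth = synth.make_gaussian_network_traj(
        synth.GaussianNetSpec(n, cov, n_frames=5000, seed=2024))
    return top, traj, corr
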