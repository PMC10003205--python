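"""Ewald summation for point charges in an orthorhombic periodic box.

Classic (non-mesh) Ewald with tinfoil (conducting) boundary conditions:
a short-range erfc part evaluated over a pair list, a reciprocal-space sum
over k-vectors, the self term, and erf corrections for intramolecular
pairs whose direct Coulomb interaction is excluded. System sizes here are
a few thousand beads at most, for which the O(N^1.5)-ish classic sum is
entirely adequate.

Energies are returned with the caller's prefactor ``f/eps_r`` already
applied (f the Coulomb constant in kJ/mol*A/e^2).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erfc

__all__ = ["EwaldParams", "ewald_params", "ewald_sum"]


_GRID_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _half_space_grid(kmax: tuple[int, int, int]) -> np.ndarray:
    """Integer k-grid over the lexicographically positive half space."""
    if kmax not in _GRID_CACHE:
        kx, ky, kz = kmax
        grids = np.meshgrid(np.arange(-kx, kx + 1), np.arange(-ky, ky + 1),
                            np.arange(-kz, kz + 1), indexing="ij")
        nvec = np.column_stack([g.ravel() for g in grids])
        keep = (
            (nvec[:, 0] > 0)
            | ((nvec[:, 0] == 0) & (nvec[:, 1] > 0))
            | ((nvec[:, 0] == 0) & (nvec[:, 1] == 0) & (nvec[:, 2] > 0))
        )
        _GRID_CACHE[kmax] = nvec[keep]
    return _GRID_CACHE[kmax]


class EwaldParams:
    """Splitting parameter and k-space extent for a target accuracy."""

    def __init__(self, alpha: float, kmax: tuple[int, int, int], accuracy: float):
        self.alpha = alpha
        self.kmax = kmax
        self.accuracy = accuracy

    def __repr__(self) -> str:  # pragma: no cover
        return f"EwaldParams(alpha={self.alpha:.4f}, kmax={self.kmax})"


def ewald_params(box: np.ndarray, r_cut: float, accuracy: float = 1e-4) -> EwaldParams:
    """Choose alpha and per-axis k-space extents.

    alpha is set so the real-space term is below ``accuracy`` at the cutoff
    (erfc(alpha r_c) ~ exp(-(alpha r_c)^2) = accuracy), and kmax so the
    reciprocal Gaussian has decayed to the same level.
    """
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must be in (0, 1)")
    s = math.sqrt(-math.log(accuracy))
    alpha = s / r_cut
    kmax = tuple(int(math.ceil(alpha * L * s / math.pi)) for L in box)
    return EwaldParams(alpha=alpha, kmax=kmax, accuracy=accuracy)


def ewald_sum(
    coords: np.ndarray,
    charges: np.ndarray,
    box: np.ndarray,
    prefactor: float,
    r_cut: float,
    params: EwaldParams,
    pair_ij: np.ndarray | None = None,
    excluded_ij: np.ndarray | None = None,
):
    """Ewald energy, forces and diagonal virial.

    Parameters
    ----------
    pair_ij : (P, 2) int array of candidate charged pairs for the real-space
        part (e.g. from the engine's neighbor list, exclusions already
        removed). If None, all charged pairs are considered.
    excluded_ij : (X, 2) pairs whose full Coulomb interaction must not be
        counted (bonded neighbors); the reciprocal sum includes them, so an
        erf correction is subtracted here.

    Returns
    -------
    (energy, forces, virial_diag) in kJ/mol, kJ/mol/A, kJ/mol.
    """
    coords = np.asarray(coords, float)
    q = np.asarray(charges, float)
    box = np.asarray(box, float)
    n = len(coords)
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    if abs(q.sum()) > 1e-8:
        raise ValueError("Ewald sum requires a neutral system")
    charged = np.abs(q) > 0
    if not charged.any():
        return 0.0, forces, virial
    alpha = params.alpha
    volume = float(np.prod(box))

    # --- real space ---------------------------------------------------------
    if pair_ij is None:
        idx = np.nonzero(charged)[0]
        ii, jj = np.triu_indices(len(idx), k=1)
        pair_ij = np.column_stack([idx[ii], idx[jj]])
        if excluded_ij is not None and len(excluded_ij):
            excl = {tuple(sorted(p)) for p in np.asarray(excluded_ij)}
            keep = [
                k for k, p in enumerate(pair_ij) if tuple(sorted(p)) not in excl
            ]
            pair_ij = pair_ij[keep]
    pair_ij = np.asarray(pair_ij, int).reshape(-1, 2)
    if len(pair_ij):
        qq = q[pair_ij[:, 0]] * q[pair_ij[:, 1]]
        live = qq != 0
        pij = pair_ij[live]
        qq = qq[live]
        if len(pij):
            d = coords[pij[:, 0]] - coords[pij[:, 1]]
            d -= np.round(d / box) * box
            r2 = np.einsum("ij,ij->i", d, d)
            inside = r2 < r_cut * r_cut
            pij, qq, d, r2 = pij[inside], qq[inside], d[inside], r2[inside]
            r = np.sqrt(r2)
            erfc_ar = erfc(alpha * r)
            e_real = prefactor * qq * erfc_ar / r
            fmag = prefactor * qq * (
                erfc_ar / r2
                + 2 * alpha / math.sqrt(math.pi) * np.exp(-(alpha * r) ** 2) / r
            ) / r
            fvec = fmag[:, None] * d
            np.add.at(forces, pij[:, 0], fvec)
            np.add.at(forces, pij[:, 1], -fvec)
            virial += np.einsum("ij,ij->j", fvec, d)
            e_real_total = float(e_real.sum())
        else:
            e_real_total = 0.0
    else:
        e_real_total = 0.0

    # --- reciprocal space ---------------------------------------------------
    nvec = _half_space_grid(params.kmax)
    kvec = 2 * math.pi * nvec / box  # (K, 3)
    k2 = np.einsum("ij,ij->i", kvec, kvec)
    # spherical cutoff: beyond k_max the Gaussian is below the accuracy target
    k2_max = (2 * alpha) ** 2 * (-math.log(params.accuracy))
    sphere = k2 <= k2_max * (1 + 1e-12)
    kvec, k2 = kvec[sphere], k2[sphere]
    ak = np.exp(-k2 / (4 * alpha * alpha)) / k2  # (K,)
    idx = np.nonzero(charged)[0]
    phase = coords[idx] @ kvec.T  # (Nc, K)
    qc = q[idx]
    cos_p = np.cos(phase)
    sin_p = np.sin(phase)
    re_s = qc @ cos_p
    im_s = qc @ sin_p
    s2 = re_s**2 + im_s**2
    coef = prefactor * 2 * math.pi / volume
    e_recip = 2 * coef * float((ak * s2).sum())  # x2 for half space

    # forces on charged beads
    fk = 2 * coef * 2 * ak * (sin_p * re_s[None, :] - cos_p * im_s[None, :])
    forces[idx] += (qc[:, None]) * (fk @ kvec)
    # virial (diagonal)
    vir_term = ak * s2
    for a in range(3):
        virial[a] += 2 * coef * float(
            (vir_term * (1 - 2 * (1 / k2 + 1 / (4 * alpha * alpha)) * kvec[:, a] ** 2)).sum()
        )

    # --- self term ----------------------------------------------------------
    e_self = -prefactor * alpha / math.sqrt(math.pi) * float((q[charged] ** 2).sum())

    # --- excluded-pair corrections ------------------------------------------
    e_corr = 0.0
    if excluded_ij is not None and len(excluded_ij):
        eij = np.asarray(excluded_ij, int).reshape(-1, 2)
        qq = q[eij[:, 0]] * q[eij[:, 1]]
        live = qq != 0
        eij, qq = eij[live], qq[live]
        if len(eij):
            d = coords[eij[:, 0]] - coords[eij[:, 1]]
            d -= np.round(d / box) * box
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            erf_ar = 1.0 - erfc(alpha * r)
            e_corr = -prefactor * float((qq * erf_ar / r).sum())
            # force of the subtracted erf interaction
            fmag = -prefactor * qq * (
                erf_ar / r**2
                - 2 * alpha / math.sqrt(math.pi) * np.exp(-(alpha * r) ** 2) / r
            ) / r
            fvec = fmag[:, None] * d
            np.add.at(forces, eij[:, 0], fvec)
            np.add.at(forces, eij[:, 1], -fvec)
            virial += np.einsum("ij,ij->j", fvec, d)

    energy = e_real_total + e_recip + e_self + e_corr
    return float(energy), forces, virial
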