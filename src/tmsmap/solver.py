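"""Quasi-static scalar-potential solve on the voxel head model.

Under the magneto-quasi-static approximation the induced scalar potential
satisfies

    div( sigma grad phi ) = -div( sigma dA/dt ),

with an insulating exterior (sigma = 0 background), and the induced
electric field is reconstructed as

    E = -grad phi - dA/dt.

The discretization is a voxel-wise finite-volume / 7-point stencil with
harmonic face-conductivity averaging: one unknown per conducting voxel
center, face flux  sigma_f (phi_j - phi_i) / h, and the right-hand side is
the discrete divergence of sigma dA/dt with face values averaged from the
two adjacent cell centers.  The scheme reproduces an affine potential
exactly, so a spatially uniform dA/dt in a homogeneous conductor yields a
vanishing electric field to solver tolerance.  The resulting matrix is
symmetric positive semi-definite with the constant vector in its null
space (pure Neumann problem); the compatible right-hand side sums to zero
and the zero-mean gauge is applied to the solution.

The system matrix depends only on the head, not on the coil placement, so
it (and its preconditioner) can be assembled once and reused across all
placements of a mapping session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coil import (
    CoilFieldCache,
    CoilModel,
    CoilPlacement,
    biot_savart_dAdt,
    wire_segments,
)
from .head import VoxelHeadModel

__all__ = [
    "LinearSystem",
    "ScalarPotentialSolution",
    "EFVolume",
    "SolverConvergenceError",
    "assemble_system",
    "solve_potential",
    "reconstruct_ef",
    "dadt_on_grid",
    "solve_placement",
    "HeadSolver",
    "export_ef_nifti",
    "export_potential_nifti",
]


class SolverConvergenceError(RuntimeError):
    """Iterative solve failed; carries the relative-residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class LinearSystem:
    """Assembled sparse system for one head model.

    ``index`` maps voxel (flat) position to unknown number (-1 outside the
    conductor); ``b`` is the right-hand side for the dA/dt field passed to
    :func:`assemble_system`.
    """

    matrix: sp.csr_matrix
    b: np.ndarray
    index: np.ndarray  # shape dims, int64, -1 where sigma == 0
    shape: tuple[int, int, int]
    voxel_size_mm: float

    @property
    def n_unknowns(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ScalarPotentialSolution:
    """Scalar potential (V) on the grid, zero-mean over conducting nodes."""

    phi: np.ndarray  # full grid, 0 outside the conductor
    conducting: np.ndarray  # boolean mask
    residual: float
    iterations: int
    residual_history: list[float] = field(default_factory=list)


@dataclass
class EFVolume:
    """Induced electric field (V/m) per voxel inside conducting tissue.

    ``E`` is zero outside the conductor; ``conducting`` marks where it is
    defined.  The stored field corresponds to ``intensity_pct_mso``.
    """

    E: np.ndarray  # dims + (3,)
    conducting: np.ndarray
    intensity_pct_mso: float
    affine: np.ndarray
    voxel_size_mm: float

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)

    def scaled(self, intensity_pct_mso: float) -> "EFVolume":
        """Field at another stimulator intensity (linear in dI/dt)."""
        factor = intensity_pct_mso / self.intensity_pct_mso
        return EFVolume(
            E=self.E * factor,
            conducting=self.conducting,
            intensity_pct_mso=intensity_pct_mso,
            affine=self.affine,
            voxel_size_mm=self.voxel_size_mm,
        )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _face_sigma(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Harmonic mean face conductivity; zero if either side is insulating."""
    num = 2.0 * sa * sb
    den = sa + sb
    out = np.zeros_like(sa)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def assemble_system(head: VoxelHeadModel, dadt: np.ndarray) -> LinearSystem:
    """Assemble the sparse scalar-potential system for one dA/dt field.

    Parameters
    ----------
    head : voxel model; must satisfy its invariants.
    dadt : dA/dt in V/m at every voxel center, shape ``dims + (3,)``.
    """
    sigma = head.sigma_volume()
    mask = sigma > 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("head model has no conducting voxels")
    if dadt.shape != head.labels.shape + (3,):
        raise ValueError(
            f"dadt shape {dadt.shape} does not match grid {head.labels.shape}"
        )

    index = -np.ones(head.labels.shape, dtype=np.int64)
    index[mask] = np.arange(n)
    h_m = head.voxel_size_mm * 1e-3

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)

        sf = _face_sigma(sigma[sl_lo], sigma[sl_hi])
        both = (index[sl_lo] >= 0) & (index[sl_hi] >= 0) & (sf > 0)
        i_lo = index[sl_lo][both]
        i_hi = index[sl_hi][both]
        sf_b = sf[both]

        rows.append(i_lo); cols.append(i_hi); vals.append(-sf_b)
        rows.append(i_hi); cols.append(i_lo); vals.append(-sf_b)
        np.add.at(diag, i_lo, sf_b)
        np.add.at(diag, i_hi, sf_b)

        # RHS: h * sum_f sigma_f (a_f . n_hat_f), outward per cell
        a_face = 0.5 * (dadt[sl_lo + (ax,)][both] + dadt[sl_hi + (ax,)][both])
        flux = h_m * sf_b * a_face
        np.add.at(b, i_lo, flux)       # +axis face of the lower cell
        np.add.at(b, i_hi, -flux)      # -axis face of the upper cell

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return LinearSystem(
        matrix=matrix,
        b=b,
        index=index,
        shape=head.labels.shape,
        voxel_size_mm=head.voxel_size_mm,
    )


def assemble_rhs(system: LinearSystem, head: VoxelHeadModel, dadt: np.ndarray) -> np.ndarray:
    """Right-hand side for a new dA/dt field on an already assembled system.

    Avoids rebuilding the (placement-independent) matrix when many coil
    placements are solved on the same head.
    """
    sigma = head.sigma_volume()
    index = system.index
    h_m = head.voxel_size_mm * 1e-3
    b = np.zeros(system.n_unknowns)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        sf = _face_sigma(sigma[sl_lo], sigma[sl_hi])
        both = (index[sl_lo] >= 0) & (index[sl_hi] >= 0) & (sf > 0)
        i_lo = index[sl_lo][both]
        i_hi = index[sl_hi][both]
        a_face = 0.5 * (dadt[sl_lo + (ax,)][both] + dadt[sl_hi + (ax,)][both])
        flux = h_m * sf[both] * a_face
        np.add.at(b, i_lo, flux)
        np.add.at(b, i_hi, -flux)
    return b


# ---------------------------------------------------------------------------
# iterative solve
# ---------------------------------------------------------------------------


def _make_preconditioner(matrix: sp.csr_matrix, kind: str):
    n = matrix.shape[0]
    if kind == "auto":
        # diagonal scaling wins in practice: CG converges in a few hundred
        # iterations on these grids and the incomplete factorization setup
        # cost dwarfs the iteration savings
        kind = "jacobi"
    if kind == "jacobi":
        inv_diag = 1.0 / matrix.diagonal()
        return lambda r: inv_diag * r
    if kind == "ilu":
        # the operator is singular (pure Neumann); a small diagonal shift
        # makes the incomplete factorization well defined without
        # meaningfully changing the preconditioner quality
        shift = 1e-4 * matrix.diagonal().mean()
        ilu = spla.spilu(
            (matrix + shift * sp.eye(n, format="csr")).tocsc(),
            drop_tol=1e-4,
            fill_factor=10.0,
        )
        return ilu.solve
    if kind == "none":
        return lambda r: r
    raise ValueError(f"unknown preconditioner {kind!r}")


def solve_potential(
    system: LinearSystem,
    tol: float = 1e-6,
    max_iter: int = 5000,
    preconditioner: str | None = "auto",
    x0: np.ndarray | None = None,
    _precond_fn=None,
) -> ScalarPotentialSolution:
    """Preconditioned conjugate-gradient solve with zero-mean gauge.

    The relative residual ``||b - A phi|| / ||b||`` is driven below ``tol``;
    non-convergence raises :class:`SolverConvergenceError` carrying the
    residual history.  ``x0`` provides a warm start (e.g. a prolonged
    coarse-grid solution).
    """
    A = system.matrix
    b = system.b
    b_norm = np.linalg.norm(b)
    if b_norm == 0:
        phi_flat = np.zeros(system.n_unknowns)
        history = [0.0]
        iters = 0
    else:
        M = _precond_fn if _precond_fn is not None else _make_preconditioner(
            A, preconditioner or "none"
        )
        x = np.zeros(system.n_unknowns) if x0 is None else np.array(x0, dtype=float)
        r = b - A @ x if x0 is not None else b.copy()
        z = M(r)
        p = z.copy()
        rz = r @ z
        history = [1.0]
        iters = 0
        for iters in range(1, max_iter + 1):
            Ap = A @ p
            alpha = rz / (p @ Ap)
            x += alpha * p
            r -= alpha * Ap
            rel = np.linalg.norm(r) / b_norm
            history.append(float(rel))
            if rel <= tol:
                break
            z = M(r)
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
        # guard against drift of the recurrence residual
        true_rel = np.linalg.norm(b - A @ x) / b_norm
        if true_rel > 10 * tol:
            raise SolverConvergenceError(
                f"CG did not converge: relative residual {true_rel:.3e} after "
                f"{iters} iterations (tol {tol:.1e})",
                history,
            )
        phi_flat = x
    phi_flat = phi_flat - phi_flat.mean()  # zero-mean gauge over conducting nodes

    conducting = system.index >= 0
    phi = np.zeros(system.shape)
    phi[conducting] = phi_flat
    return ScalarPotentialSolution(
        phi=phi,
        conducting=conducting,
        residual=float(history[-1]),
        iterations=iters,
        residual_history=history,
    )


# ---------------------------------------------------------------------------
# field reconstruction
# ---------------------------------------------------------------------------


def _masked_gradient(phi: np.ndarray, mask: np.ndarray, h_m: float) -> np.ndarray:
    """Gradient of phi inside ``mask``: central differences where both
    neighbors conduct, one-sided at tissue boundaries, zero where isolated."""
    grad = np.zeros(phi.shape + (3,))
    for ax in range(3):
        lo = np.zeros_like(phi, dtype=bool)
        hi = np.zeros_like(phi, dtype=bool)
        sl_int = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_int[ax] = slice(1, None)
        sl_m[ax] = slice(None, -1)
        lo[tuple(sl_int)] = mask[tuple(sl_m)]   # neighbor below exists
        hi[tuple(sl_m)] = mask[tuple(sl_int)]   # neighbor above exists

        phi_up = np.roll(phi, -1, axis=ax)
        phi_dn = np.roll(phi, +1, axis=ax)

        g = np.zeros_like(phi)
        both = mask & lo & hi
        only_hi = mask & hi & ~lo
        only_lo = mask & lo & ~hi
        g[both] = (phi_up[both] - phi_dn[both]) / (2.0 * h_m)
        g[only_hi] = (phi_up[only_hi] - phi[only_hi]) / h_m
        g[only_lo] = (phi[only_lo] - phi_dn[only_lo]) / h_m
        grad[..., ax] = g
    return grad


def reconstruct_ef(
    solution: ScalarPotentialSolution,
    dadt: np.ndarray,
    head: VoxelHeadModel,
    intensity_pct_mso: float = 100.0,
) -> EFVolume:
    """E = -grad(phi) - dA/dt inside conducting tissue, scaled to %MSO.

    ``dadt`` must be the field the potential was solved with (the 100 %MSO
    field in the standard pipeline); the stored volume is scaled by
    ``intensity_pct_mso / 100``.
    """
    if solution.phi.shape != head.labels.shape:
        raise ValueError("potential grid does not match the head model grid")
    if dadt.shape != head.labels.shape + (3,):
        raise ValueError("dadt grid does not match the head model grid")
    mask = solution.conducting
    h_m = head.voxel_size_mm * 1e-3
    E = -_masked_gradient(solution.phi, mask, h_m)
    E[mask] -= dadt[mask]
    E[~mask] = 0.0
    E *= intensity_pct_mso / 100.0
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("non-finite electric field values")
    return EFVolume(
        E=E,
        conducting=mask,
        intensity_pct_mso=intensity_pct_mso,
        affine=head.affine,
        voxel_size_mm=head.voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------


def dadt_on_grid(
    head: VoxelHeadModel,
    coil: CoilModel,
    placement: CoilPlacement,
    didt_A_per_us: float | None = None,
    restrict_to_conductor: bool = True,
    cache: "CoilFieldCache | None" = None,
) -> np.ndarray:
    """Evaluate the coil dA/dt at voxel centers of the head grid.

    With ``restrict_to_conductor`` the Biot-Savart sum is evaluated only at
    conducting voxels — all the solver uses, since both the right-hand side
    and the reconstruction weight dA/dt by face/voxel conductivities that
    vanish wherever a non-conducting voxel is involved.  This is
    several-fold cheaper than the full grid.
    """
    if didt_A_per_us is None:
        didt_A_per_us = coil.didt(placement.intensity_pct_mso)
    centers = head.voxel_centers_world()
    dadt = np.zeros(head.labels.shape + (3,))
    if restrict_to_conductor:
        need = head.sigma_volume() > 0
    else:
        need = np.ones(head.labels.shape, dtype=bool)
    if cache is not None:
        dadt[need] = cache.evaluate(placement, centers[need], didt_A_per_us)
    else:
        mids, dls = wire_segments(coil, placement)
        dadt[need] = biot_savart_dAdt(mids, dls, centers[need], didt_A_per_us)
    return dadt


class HeadSolver:
    """Reusable solver for one head: assemble and precondition once,
    then solve many coil placements.

    All placements are solved at 100 %MSO (dI/dt = coil rating); fields at
    other intensities follow by linear scaling via :meth:`EFVolume.scaled`.

    Two optional accelerations for many-placement sessions: a coil-frame
    dA/dt cache (``use_cache``), and a coarse companion head model
    (``coarse_head``) whose solution is prolonged as a warm start for the
    fine conjugate-gradient solve.
    """

    def __init__(
        self,
        head: VoxelHeadModel,
        coil: CoilModel | None = None,
        tol: float = 1e-6,
        preconditioner: str = "auto",
        use_cache: bool = False,
        coarse_head: VoxelHeadModel | None = None,
    ):
        self.head = head
        self.coil = coil or CoilModel()
        self.tol = tol
        zero = np.zeros(head.labels.shape + (3,))
        self._system = assemble_system(head, zero)
        self._precond = _make_preconditioner(self._system.matrix, preconditioner)
        self._cache = None
        if use_cache:
            extent = 0.5 * head.voxel_size_mm * max(head.dims)
            self._cache = CoilFieldCache(self.coil, extent_mm=extent)
        self._coarse = None
        if coarse_head is not None:
            self._coarse = {
                "head": coarse_head,
                "system": assemble_system(
                    coarse_head, np.zeros(coarse_head.labels.shape + (3,))
                ),
            }
            self._coarse["precond"] = _make_preconditioner(
                self._coarse["system"].matrix, preconditioner
            )
        self._prev_fine: np.ndarray | None = None
        self._prev_coarse_prolonged: np.ndarray | None = None

    def _prolong(self, phi_coarse: np.ndarray) -> np.ndarray:
        """Sample a coarse-grid potential at the fine conducting centers."""
        from scipy import ndimage

        ch: VoxelHeadModel = self._coarse["head"]
        centers = self.head.voxel_centers_world()[self._system.index >= 0]
        inv = np.linalg.inv(ch.affine)
        idx = centers @ inv[:3, :3].T + inv[:3, 3] - 0.5
        return ndimage.map_coordinates(phi_coarse, idx.T, order=1)

    def _warm_start(self, placement: CoilPlacement) -> np.ndarray | None:
        """Initial guess for the fine solve.

        A 2x coarser companion solve is prolonged to the fine grid; when a
        previous placement has been solved, its fine solution corrected by
        the coarse *increment* is usually closer still (adjacent protocol
        placements differ by a 5 mm shift).  The candidate guesses are
        deterministic, so the solve sequence remains reproducible.
        """
        if self._coarse is None:
            return None
        ch: VoxelHeadModel = self._coarse["head"]
        csys: LinearSystem = self._coarse["system"]
        dadt_c = dadt_on_grid(
            ch, self.coil, placement, self.coil.didt_at_100pct, cache=self._cache
        )
        sys_c = LinearSystem(
            csys.matrix, assemble_rhs(csys, ch, dadt_c),
            csys.index, csys.shape, csys.voxel_size_mm,
        )
        sol_c = solve_potential(
            sys_c, tol=1e-5, _precond_fn=self._coarse["precond"]
        )
        pc = self._prolong(sol_c.phi)
        x0 = pc
        if self._prev_fine is not None:
            x0 = self._prev_fine + (pc - self._prev_coarse_prolonged)
        self._prev_coarse_prolonged = pc
        return x0 - x0.mean()

    def solve(self, placement: CoilPlacement) -> EFVolume:
        dadt = dadt_on_grid(
            self.head, self.coil, placement, self.coil.didt_at_100pct,
            cache=self._cache,
        )
        system = LinearSystem(
            matrix=self._system.matrix,
            b=assemble_rhs(self._system, self.head, dadt),
            index=self._system.index,
            shape=self._system.shape,
            voxel_size_mm=self._system.voxel_size_mm,
        )
        sol = solve_potential(
            system, tol=self.tol, x0=self._warm_start(placement),
            _precond_fn=self._precond,
        )
        if self._coarse is not None:
            self._prev_fine = sol.phi[system.index >= 0]
        return reconstruct_ef(sol, dadt, self.head, intensity_pct_mso=100.0)


def solve_placement(
    head: VoxelHeadModel,
    coil: CoilModel,
    placement: CoilPlacement,
    tol: float = 1e-6,
    preconditioner: str = "auto",
    intensity_pct_mso: float | None = None,
) -> EFVolume:
    """One-shot solve of a single placement (assembles everything itself)."""
    dadt = dadt_on_grid(head, coil, placement, coil.didt_at_100pct)
    system = assemble_system(head, dadt)
    sol = solve_potential(system, tol=tol, preconditioner=preconditioner)
    ef100 = reconstruct_ef(sol, dadt, head, intensity_pct_mso=100.0)
    pct = intensity_pct_mso or placement.intensity_pct_mso
    return ef100.scaled(pct)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_ef_nifti(ef: EFVolume, path: str | Path) -> None:
    """4D NIfTI with the three field components (V/m)."""
    nib.save(nib.Nifti1Image(ef.E.astype(np.float32), ef.affine), str(path))


def export_potential_nifti(
    solution: ScalarPotentialSolution, affine: np.ndarray, path: str | Path
) -> None:
    nib.save(nib.Nifti1Image(solution.phi.astype(np.float32), affine), str(path))
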