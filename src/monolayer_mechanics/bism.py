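"""Monolayer stress inference by regularised inversion of force balance.

A thin adherent monolayer in mechanical quasi-equilibrium satisfies
``div σ = t``, where σ is the 2D (height-integrated) stress tensor in
Pa·µm and t the traction the monolayer exerts on its substrate in Pa.
Traction is measurable (TFM); σ is not, and the force balance alone leaves
the stress underdetermined.  Following the Bayesian-inversion approach,
the estimate minimises

    ‖A σ − t‖² + Λ ‖σ‖²

in nondimensional variables (traction scaled by its RMS over valid nodes,
lengths by the grid spacing), where A is the discrete divergence operator
and Λ a dimensionless regularisation weight (default 1e-6).  Free-stress
boundary conditions (σ·n = 0) are imposed as *hard* linear constraints on
the designated cell-free edge only; the other edges are left
unconstrained, which does not affect estimates away from the boundaries —
hence the downstream practice of discarding a 200 µm bulk margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import (
    EstimationError,
    GeometryError,
    GridSpec,
    ParameterError,
    StressField,
    VectorField2D,
)

__all__ = ["BismConfig", "assemble_force_balance", "infer_stress", "residual_report"]

_EDGES = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class BismConfig:
    """Inversion settings.

    ``lambda_``: dimensionless Tikhonov weight Λ.  ``free_edges``: edges on
    which σ·n = 0 is enforced exactly (normally just the cell-free side,
    e.g. ``("right",)`` for a front advancing in +x).
    """

    lambda_: float = 1e-6
    free_edges: tuple[str, ...] = ("right",)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ParameterError("lambda must be >= 0")
        for e in self.free_edges:
            if e not in _EDGES:
                raise ParameterError(f"unknown edge {e!r}; use one of {_EDGES}")


def _diff_matrix(n: int, h: float) -> sp.csr_matrix:
    """1D first-derivative: centred interior, one-sided at the ends.

    Both stencils are exact on linear functions.
    """
    rows, cols, vals = [], [], []
    for i in range(n):
        if i == 0:
            rows += [i, i]
            cols += [0, 1]
            vals += [-1.0 / h, 1.0 / h]
        elif i == n - 1:
            rows += [i, i]
            cols += [n - 2, n - 1]
            vals += [-1.0 / h, 1.0 / h]
        else:
            rows += [i, i]
            cols += [i - 1, i + 1]
            vals += [-0.5 / h, 0.5 / h]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def assemble_force_balance(grid: GridSpec) -> sp.csr_matrix:
    """Sparse operator mapping stress DOFs to traction components.

    Stress DOFs are ordered ``[sxx (N), syy (N), sxy (N)]`` with nodes
    flattened row-major (N = n_y·n_x); the output stacks ``[t_x (N),
    t_y (N)]``:

        t_x = ∂x σxx + ∂y σxy
        t_y = ∂x σxy + ∂y σyy
    """
    if grid.n_x < 8 or grid.n_y < 8:
        raise ParameterError("force balance needs a grid of at least 8x8 nodes")
    n_y, n_x = grid.n_y, grid.n_x
    h = grid.spacing
    Ix = sp.identity(n_x, format="csr")
    Iy = sp.identity(n_y, format="csr")
    Dx = sp.kron(Iy, _diff_matrix(n_x, h), format="csr")  # ∂/∂x on row-major fields
    Dy = sp.kron(_diff_matrix(n_y, h), Ix, format="csr")  # ∂/∂y
    N = n_y * n_x
    Z = sp.csr_matrix((N, N))
    top = sp.hstack([Dx, Z, Dy], format="csr")  # t_x rows
    bot = sp.hstack([Z, Dy, Dx], format="csr")  # t_y rows
    return sp.vstack([top, bot], format="csr")


def _free_edge_dofs(grid: GridSpec, edges: tuple[str, ...]) -> np.ndarray:
    """Indices of stress DOFs pinned to zero by σ·n = 0 on the given edges."""
    n_y, n_x = grid.n_y, grid.n_x
    N = n_y * n_x
    idx = np.arange(N).reshape(n_y, n_x)
    pinned: set[int] = set()
    for e in edges:
        if e == "left":
            nodes = idx[:, 0]
            comps = (0, 2)  # sxx, sxy
        elif e == "right":
            nodes = idx[:, -1]
            comps = (0, 2)
        elif e == "top":
            nodes = idx[0, :]
            comps = (1, 2)  # syy, sxy
        else:  # bottom
            nodes = idx[-1, :]
            comps = (1, 2)
        for c in comps:
            pinned.update((c * N + nodes).tolist())
    return np.array(sorted(pinned), dtype=int)


def infer_stress(
    traction: VectorField2D, cfg: BismConfig = BismConfig()
) -> StressField:
    """Estimate the monolayer stress tensor from the traction field.

    Minimises ``‖A σ' − t'‖² + Λ ‖σ'‖²`` in nondimensional variables
    (t' = t / t_rms, lengths in grid spacings, σ' = σ / (t_rms·spacing)),
    with the free-edge DOFs eliminated (σ·n = 0 holds exactly there).
    Returns σ in Pa·µm on the traction grid.

    With Λ = 0 the data-consistent minimum-norm solution is computed
    iteratively (LSQR); the system is otherwise rank-deficient, and a
    Λ = 0 *direct* solve is refused.
    """
    if traction.unit != "Pa":
        raise ParameterError("traction must carry unit 'Pa'")
    grid = traction.grid
    n_y, n_x = grid.shape
    N = n_y * n_x
    t_rms = float(np.sqrt(np.mean(traction.u[traction.valid] ** 2 +
                                  traction.v[traction.valid] ** 2)))
    if t_rms == 0:
        # zero traction: the regularised minimum-norm solution is σ = 0
        z = np.zeros(grid.shape)
        return StressField(grid=grid, sxx=z, syy=z.copy(), sxy=z.copy())

    # nondimensional operator: unit spacing
    ngrid = GridSpec(origin=(0.0, 0.0), n_x=n_x, n_y=n_y, spacing=1.0)
    A = assemble_force_balance(ngrid)
    b = np.concatenate([traction.u.ravel(), traction.v.ravel()]) / t_rms

    pinned = _free_edge_dofs(grid, cfg.free_edges)
    keep = np.setdiff1d(np.arange(3 * N), pinned)
    Ak = A[:, keep]

    lam = cfg.lambda_
    if lam > 0:
        AtA = (Ak.T @ Ak).tocsc()
        reg = AtA + lam * sp.identity(Ak.shape[1], format="csc")
        x = spla.spsolve(reg, Ak.T @ b)
    else:
        if len(pinned) == 0:
            raise EstimationError(
                "force balance at Λ = 0 without boundary constraints is "
                "ill-posed: set Λ > 0 or designate a free edge"
            )
        # minimum-norm least squares; rank deficiency is handled by LSQR
        x = spla.lsqr(Ak, b, atol=1e-12, btol=1e-12, iter_lim=20000)[0]

    sigma = np.zeros(3 * N)
    sigma[keep] = x
    scale = t_rms * grid.spacing  # back to Pa·µm
    sxx = sigma[:N].reshape(n_y, n_x) * scale
    syy = sigma[N : 2 * N].reshape(n_y, n_x) * scale
    sxy = sigma[2 * N :].reshape(n_y, n_x) * scale
    return StressField(grid=grid, sxx=sxx, syy=syy, sxy=sxy)


def residual_report(
    traction: VectorField2D, stress: StressField
) -> tuple[float, VectorField2D]:
    """Force-balance residual of an inferred stress field.

    Returns ``(relative_residual, residual_field)`` where the scalar is
    ‖A σ − t‖ / ‖t‖ (absolute and flagged by a NaN-free convention when
    ‖t‖ = 0) and the field maps the per-node residual components.
    """
    if not traction.grid.same_geometry(stress.grid):
        raise GeometryError("traction and stress grids do not match")
    grid = traction.grid
    A = assemble_force_balance(grid)
    sigma = np.concatenate([stress.sxx.ravel(), stress.syy.ravel(), stress.sxy.ravel()])
    t = np.concatenate([traction.u.ravel(), traction.v.ravel()])
    r = A @ sigma - t
    t_norm = np.linalg.norm(t)
    rel = float(np.linalg.norm(r) / t_norm) if t_norm > 0 else float(np.linalg.norm(r))
    N = grid.n_y * grid.n_x
    res_field = VectorField2D(
        grid=grid,
        u=r[:N].reshape(grid.shape),
        v=r[N:].reshape(grid.shape),
        unit="Pa",
    )
    return rel, res_field
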