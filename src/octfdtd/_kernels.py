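"""Numba-compiled stepping kernels (loop-fused version of Solver.step).

The kernels reproduce the vectorised numpy update exactly — same operation
order per element — but fuse the passes, which matters on large grids where
the numpy path is memory-bandwidth bound.  The numpy path remains as a
fallback when numba is unavailable.
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def step_pec(
    E, H1, H2, ce, ch, inv_dx, inv_dy,
    xL, b_e_xlo, c_e_xlo, b_h_xlo, c_h_xlo, b_e_xhi, c_e_xhi, b_h_xhi, c_h_xhi,
    psi_h2_lo, psi_h2_hi, psi_e_xlo, psi_e_xhi,
    yL, b_e_ylo, c_e_ylo, b_h_ylo, c_h_ylo, b_e_yhi, c_e_yhi, b_h_yhi, c_h_yhi,
    psi_h1_lo, psi_h1_hi, psi_e_ylo_a, psi_e_yhi_a,
):
    nx, ny = E.shape
    # H1 (y-staggered): H1[i,j] at (i, j+1/2)
    for i in range(nx):
        for j in range(ny - 1):
            H1[i, j] -= ch * (E[i, j + 1] - E[i, j]) * inv_dy
    for i in range(nx):
        for j in range(yL):
            d = (E[i, j + 1] - E[i, j]) * inv_dy
            psi_h1_lo[i, j] = b_h_ylo[j] * psi_h1_lo[i, j] + c_h_ylo[j] * d
            H1[i, j] -= ch * psi_h1_lo[i, j]
        for m in range(yL):
            j = ny - 1 - yL + m
            d = (E[i, j + 1] - E[i, j]) * inv_dy
            psi_h1_hi[i, m] = b_h_yhi[m] * psi_h1_hi[i, m] + c_h_yhi[m] * d
            H1[i, j] -= ch * psi_h1_hi[i, m]
    # H2 (x-staggered): H2[i,j] at (i+1/2, j)
    for i in range(nx - 1):
        for j in range(ny):
            H2[i, j] += ch * (E[i + 1, j] - E[i, j]) * inv_dx
    for i in range(xL):
        for j in range(ny):
            d = (E[i + 1, j] - E[i, j]) * inv_dx
            psi_h2_lo[i, j] = b_h_xlo[i] * psi_h2_lo[i, j] + c_h_xlo[i] * d
            H2[i, j] += ch * psi_h2_lo[i, j]
    for m in range(xL):
        i = nx - 1 - xL + m
        for j in range(ny):
            d = (E[i + 1, j] - E[i, j]) * inv_dx
            psi_h2_hi[m, j] = b_h_xhi[m] * psi_h2_hi[m, j] + c_h_xhi[m] * d
            H2[i, j] += ch * psi_h2_hi[m, j]
    # E from curl H
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            dhx = (H1[i, j] - H1[i, j - 1]) * inv_dy
            E[i, j] += ce[i, j] * (dhy - dhx)
    for i in range(1, xL):
        for j in range(1, ny - 1):
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            psi_e_xlo[i - 1, j - 1] = (
                b_e_xlo[i - 1] * psi_e_xlo[i - 1, j - 1] + c_e_xlo[i - 1] * dhy
            )
            E[i, j] += ce[i, j] * psi_e_xlo[i - 1, j - 1]
    for m in range(max(xL - 1, 0)):
        i = nx - xL + m
        for j in range(1, ny - 1):
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            psi_e_xhi[m, j - 1] = b_e_xhi[m] * psi_e_xhi[m, j - 1] + c_e_xhi[m] * dhy
            E[i, j] += ce[i, j] * psi_e_xhi[m, j - 1]
    for i in range(1, nx - 1):
        for j in range(1, yL):
            dhx = (H1[i, j] - H1[i, j - 1]) * inv_dy
            psi_e_ylo_a[i - 1, j - 1] = (
                b_e_ylo[j - 1] * psi_e_ylo_a[i - 1, j - 1] + c_e_ylo[j - 1] * dhx
            )
            E[i, j] -= ce[i, j] * psi_e_ylo_a[i - 1, j - 1]
        for m in range(max(yL - 1, 0)):
            j = ny - yL + m
            dhx = (H1[i, j] - H1[i, j - 1]) * inv_dy
            psi_e_yhi_a[i - 1, m] = b_e_yhi[m] * psi_e_yhi_a[i - 1, m] + c_e_yhi[m] * dhx
            E[i, j] -= ce[i, j] * psi_e_yhi_a[i - 1, m]


@njit(cache=True)
def step_periodic(
    E, H1, H2, ce, ch, inv_dx, inv_dy,
    xL, b_e_xlo, c_e_xlo, b_h_xlo, c_h_xlo, b_e_xhi, c_e_xhi, b_h_xhi, c_h_xhi,
    psi_h2_lo, psi_h2_hi, psi_e_xlo, psi_e_xhi,
):
    nx, ny = E.shape
    # H1 with wraparound in y: H1[i,j] at (i, j+1/2), neighbour (j+1) mod ny
    for i in range(nx):
        for j in range(ny - 1):
            H1[i, j] -= ch * (E[i, j + 1] - E[i, j]) * inv_dy
        H1[i, ny - 1] -= ch * (E[i, 0] - E[i, ny - 1]) * inv_dy
    for i in range(nx - 1):
        for j in range(ny):
            H2[i, j] += ch * (E[i + 1, j] - E[i, j]) * inv_dx
    for i in range(xL):
        for j in range(ny):
            d = (E[i + 1, j] - E[i, j]) * inv_dx
            psi_h2_lo[i, j] = b_h_xlo[i] * psi_h2_lo[i, j] + c_h_xlo[i] * d
            H2[i, j] += ch * psi_h2_lo[i, j]
    for m in range(xL):
        i = nx - 1 - xL + m
        for j in range(ny):
            d = (E[i + 1, j] - E[i, j]) * inv_dx
            psi_h2_hi[m, j] = b_h_xhi[m] * psi_h2_hi[m, j] + c_h_xhi[m] * d
            H2[i, j] += ch * psi_h2_hi[m, j]
    for i in range(1, nx - 1):
        for j in range(ny):
            jm = j - 1 if j > 0 else ny - 1
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            dhx = (H1[i, j] - H1[i, jm]) * inv_dy
            E[i, j] += ce[i, j] * (dhy - dhx)
    for i in range(1, xL):
        for j in range(ny):
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            psi_e_xlo[i - 1, j] = b_e_xlo[i - 1] * psi_e_xlo[i - 1, j] + c_e_xlo[i - 1] * dhy
            E[i, j] += ce[i, j] * psi_e_xlo[i - 1, j]
    for m in range(max(xL - 1, 0)):
        i = nx - xL + m
        for j in range(ny):
            dhy = (H2[i, j] - H2[i - 1, j]) * inv_dx
            psi_e_xhi[m, j] = b_e_xhi[m] * psi_e_xhi[m, j] + c_e_xhi[m] * dhy
            E[i, j] += ce[i, j] * psi_e_xhi[m, j]
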