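"""Numba kernels for the momentum tendencies on the staggered grid.

Neighbor codes (per face, per direction) encode how a missing staggered
neighbor is reconstructed:

* 0 READ     - neighbor face carries a value (active or open-normal face)
* 1 ZERO     - impermeable wall face in the normal direction (no-slip)
* 2 REFLECT  - tangential wall at the cell boundary: ghost = -self
* 3 ZGRAD    - open boundary in the tangential direction: ghost = self

Advection is 2nd-order upwind with a van Leer limiter (falls back to
1st-order where the second upwind neighbor is not readable); diffusion is
central with the same ghost rules.
"""
import numba as nb

READ, ZERO, REFLECT, ZGRAD = 0, 1, 2, 3


@nb.njit(cache=True, inline="always")
def _limited(d1, d0):
    """Limited 2nd-order upwind increment: d1 + 0.5*phi(r)*(d1-d0)."""
    if d0 * d1 <= 0.0:
        return d1
    r = d0 / d1
    phi = (r + abs(r)) / (1.0 + abs(r))
    return d1 + 0.5 * phi * (d1 - d0)


@nb.njit(cache=True, fastmath=True)
def tend_u(u, v, jj, ii, cL, cR, cD, cU, ok2L, ok2R, ok2D, ok2U,
           h, nu, order, out):
    """Advective + diffusive tendency for the x-velocity faces."""
    for k in range(jj.size):
        j = jj[k]
        i = ii[k]
        uc = u[j, i]

        if cL[k] == 0:
            uL = u[j, i - 1]
        elif cL[k] == 1:
            uL = 0.0
        elif cL[k] == 2:
            uL = -uc
        else:
            uL = uc
        if cR[k] == 0:
            uR = u[j, i + 1]
        elif cR[k] == 1:
            uR = 0.0
        elif cR[k] == 2:
            uR = -uc
        else:
            uR = uc
        if cD[k] == 0:
            uD = u[j - 1, i]
        elif cD[k] == 1:
            uD = 0.0
        elif cD[k] == 2:
            uD = -uc
        else:
            uD = uc
        if cU[k] == 0:
            uU = u[j + 1, i]
        elif cU[k] == 1:
            uU = 0.0
        elif cU[k] == 2:
            uU = -uc
        else:
            uU = uc

        vbar = 0.25 * (v[j, i - 1] + v[j, i] + v[j + 1, i - 1] + v[j + 1, i])

        a = uc
        if a >= 0.0:
            d1 = uc - uL
            if order == 2 and ok2L[k]:
                dudx = _limited(d1, uL - u[j, i - 2]) / h
            else:
                dudx = d1 / h
        else:
            d1 = uR - uc
            if order == 2 and ok2R[k]:
                dudx = _limited(d1, u[j, i + 2] - uR) / h
            else:
                dudx = d1 / h

        if vbar >= 0.0:
            d1 = uc - uD
            if order == 2 and ok2D[k]:
                dudy = _limited(d1, uD - u[j - 2, i]) / h
            else:
                dudy = d1 / h
        else:
            d1 = uU - uc
            if order == 2 and ok2U[k]:
                dudy = _limited(d1, u[j + 2, i] - uU) / h
            else:
                dudy = d1 / h

        adv = -(a * dudx + vbar * dudy)
        diff = nu * (uL + uR + uD + uU - 4.0 * uc) / (h * h)
        out[j, i] = adv + diff


@nb.njit(cache=True, fastmath=True)
def tend_v(u, v, jj, ii, cL, cR, cD, cU, ok2L, ok2R, ok2D, ok2U,
           h, nu, order, out):
    """Advective + diffusive tendency for the y-velocity faces."""
    for k in range(jj.size):
        j = jj[k]
        i = ii[k]
        vc = v[j, i]

        if cL[k] == 0:
            vL = v[j, i - 1]
        elif cL[k] == 1:
            vL = 0.0
        elif cL[k] == 2:
            vL = -vc
        else:
            vL = vc
        if cR[k] == 0:
            vR = v[j, i + 1]
        elif cR[k] == 1:
            vR = 0.0
        elif cR[k] == 2:
            vR = -vc
        else:
            vR = vc
        if cD[k] == 0:
            vD = v[j - 1, i]
        elif cD[k] == 1:
            vD = 0.0
        elif cD[k] == 2:
            vD = -vc
        else:
            vD = vc
        if cU[k] == 0:
            vU = v[j + 1, i]
        elif cU[k] == 1:
            vU = 0.0
        elif cU[k] == 2:
            vU = -vc
        else:
            vU = vc

        ubar = 0.25 * (u[j - 1, i] + u[j - 1, i + 1] + u[j, i] + u[j, i + 1])

        if ubar >= 0.0:
            d1 = vc - vL
            if order == 2 and ok2L[k]:
                dvdx = _limited(d1, vL - v[j, i - 2]) / h
            else:
                dvdx = d1 / h
        else:
            d1 = vR - vc
            if order == 2 and ok2R[k]:
                dvdx = _limited(d1, v[j, i + 2] - vR) / h
            else:
                dvdx = d1 / h

        b = vc
        if b >= 0.0:
            d1 = vc - vD
            if order == 2 and ok2D[k]:
                dvdy = _limited(d1, vD - v[j - 2, i]) / h
            else:
                dvdy = d1 / h
        else:
            d1 = vU - vc
            if order == 2 and ok2U[k]:
                dvdy = _limited(d1, v[j + 2, i] - vU) / h
            else:
                dvdy = d1 / h

        adv = -(ubar * dvdx + b * dvdy)
        diff = nu * (vL + vR + vD + vU - 4.0 * vc) / (h * h)
        out[j, i] = adv + diff
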