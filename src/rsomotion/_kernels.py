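"""Numba-compiled inner loop of the delay-and-sum beamformer.

Semantics are identical to ``rsomotion.recon._das_numpy`` (the pure
numpy reference); the test suite cross-checks the two on a small case.
"""

from __future__ import annotations

import math

import numba


@numba.njit(cache=False, fastmath=True)
def das_kernel(data, x_s, y_s, focal_z, t0_samp, samp_per_um, tan_half,
               xv, yv, zv, out):  # pragma: no cover - compiled
    n_ss, n_fs, n_t = data.shape
    nx = xv.size
    ny = yv.size
    nz = zv.size
    z_last = zv[nz - 1]
    for iss in range(n_ss):
        ys = y_s[iss]
        for ifs in range(n_fs):
            xs = x_s[ifs]
            trace = data[iss, ifs]
            fz = focal_z[iss, ifs]
            # largest acceptance radius over the z range
            zmax = abs(z_last - fz)
            if abs(zv[0] - fz) > zmax:
                zmax = abs(zv[0] - fz)
            rmax = tan_half * zmax
            rmax2 = rmax * rmax
            for ix in range(nx):
                dx = xv[ix] - xs
                if dx * dx > rmax2:
                    continue
                for iy in range(ny):
                    dy = yv[iy] - ys
                    q2 = dx * dx + dy * dy
                    if q2 > rmax2:
                        continue
                    for iz in range(nz):
                        dzv = zv[iz] - fz
                        if dzv == 0.0:
                            continue
                        lim = tan_half * abs(dzv)
                        if q2 > lim * lim:
                            continue
                        r = math.sqrt(q2 + dzv * dzv)
                        if dzv > 0.0:
                            a = t0_samp + r * samp_per_um
                        else:
                            a = t0_samp - r * samp_per_um
                        i0 = int(math.floor(a))
                        if i0 < 0 or i0 >= n_t - 1:
                            continue
                        frac = a - i0
                        out[ix, iy, iz] += (1.0 - frac) * trace[i0] + frac * trace[i0 + 1]
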