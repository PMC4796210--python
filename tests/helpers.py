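"""Independent oracle implementations used by the tests.

These deliberately re-derive quantities with plain loops and a separate
transcription of the energy model, so they check the vectorized package
code rather than mirroring it.
"""

import math

import numpy as np

from hydrosite.structures import vdw_parameters


def naive_probe_energy(point, env, probe):
    """Plain double-loop transcription of the probe energy model.

    E = sum over atoms of LJ(12-6, Lorentz-Berthelot) + Coulomb with
    eps_r = 4r + directional 12-10 H-bond (depth 4 at 2.9 A, cos^2 lobe
    factor where the atom carries lobes), clamped at +100.
    """
    total = 0.0
    for i in range(len(env)):
        d = np.asarray(point, dtype=float) - env.positions[i]
        r = max(float(np.linalg.norm(d)), 1e-6)
        if probe.vdw_epsilon > 0:
            eps = math.sqrt(probe.vdw_epsilon * env.epsilon[i])
            rmin = probe.vdw_rmin / 2.0 + env.rmin_half[i]
            total += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
        if probe.charge != 0.0 and env.charge[i] != 0.0:
            total += 332.06 * probe.charge * env.charge[i] / (4.0 * r * r)
        if probe.hbond_capable and env.role[i] != 0:
            x = 2.9 / r
            base = 4.0 * (5.0 * x**12 - 6.0 * x**10)
            lobes = env.lobes[i]
            if lobes is None:
                factor = 1.0
            else:
                u = d / r  # from the atom toward the probe point
                best = 0.0
                for lobe in lobes:
                    c = float(np.dot(lobe, u))
                    if c > best:
                        best = c
                factor = best * best
            total += base * factor
    return min(total, 100.0)


def brute_force_hbond_pairs(waters):
    """Independent enumeration of water-water H-bond pairs.

    Criteria: O...O <= 3.5 A and some donor H with a D-H...A angle of at
    least 120 degrees, checked in both directions.
    """
    pairs = []
    for i in range(len(waters)):
        for j in range(i + 1, len(waters)):
            wi, wj = waters[i], waters[j]
            if np.linalg.norm(wi.oxygen - wj.oxygen) > 3.5:
                continue
            ok = False
            for donor, acceptor in ((wi, wj), (wj, wi)):
                for h in (donor.h1, donor.h2):
                    v1 = donor.oxygen - h
                    v2 = acceptor.oxygen - h
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = math.degrees(math.acos(float(np.clip(cosang, -1, 1))))
                    if ang >= 120.0:
                        ok = True
            if ok:
                pairs.append((i, j))
    return pairs


def quadrature_delta_f(potential, temperature, bound_x=1.0, start_x=0.0,
                       window=0.3, n=20001):
    """Trapezoid-rule Boltzmann quadrature, independent of scipy.quad."""
    kt = 0.0019872041 * temperature

    def z(center):
        xs = np.linspace(center - window, center + window, n)
        return np.trapezoid(np.exp(-potential(xs) / kt), xs)

    return -kt * math.log(z(bound_x) / z(start_x))
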