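"""Independent Monte Carlo oracle for slab transmittance.

Isotropic random-walk photon transport, written deliberately without
reference to the diffusion closed form it checks: exponential step lengths
of mean 1/mu_s', continuous absorption weighting exp(-mu_a * path),
unpolarized Fresnel internal reflection at both faces from the refractive
index mismatch (specular continuation of the remaining flight), and exit
time = in-medium path length / c.
"""

from __future__ import annotations

import numpy as np

C0 = 29.9792458  # cm/ns


def _fresnel_reflectance(cos_i: np.ndarray, n_in: float, n_out: float = 1.0) -> np.ndarray:
    """Unpolarized Fresnel power reflectance for internal incidence."""
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - cos_i**2)
    r = np.ones_like(cos_i)  # total internal reflection
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(1.0 - sin_t2[ok])
    ci = cos_i[ok]
    rs = ((n_in * ci - n_out * cos_t) / (n_in * ci + n_out * cos_t)) ** 2
    rp = ((n_in * cos_t - n_out * ci) / (n_in * cos_t + n_out * ci)) ** 2
    r[ok] = 0.5 * (rs + rp)
    return r


def mc_transmitted_photons(
    mu_a: float,
    mu_s_prime: float,
    n_medium: float,
    z_d: float,
    n_photons: int,
    seed: int,
    *,
    fresnel: bool = True,
    max_steps: int | None = None,
):
    """Random-walk transport through the slab [0, z_d].

    A pencil beam enters at the origin travelling +z; each scattering event
    redirects the photon isotropically with exponential free paths of mean
    1/mu_s_prime. Returns (times_ns, weights, exit_radius_cm) for photons
    leaving through the far face.
    """
    rng = np.random.default_rng(seed)
    mfp = 1.0 / mu_s_prime
    c = C0 / n_medium
    if max_steps is None:
        max_steps = int(40 * (z_d / mfp) ** 2 + 200)

    pos = np.zeros((n_photons, 3))
    dirs = np.zeros((n_photons, 3))
    dirs[:, 2] = 1.0  # collimated entry
    path = np.zeros(n_photons)
    alive = np.ones(n_photons, dtype=bool)

    out_t, out_w, out_r = [], [], []

    for _ in range(max_steps):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        remaining = np.zeros(n_photons)
        remaining[idx] = rng.exponential(mfp, size=idx.size)
        flying = idx
        # propagate this flight, allowing several specular boundary bounces
        for _bounce in range(8):
            if flying.size == 0:
                break
            rem = remaining[flying]
            dz = dirs[flying, 2]
            with np.errstate(divide="ignore", invalid="ignore"):
                s_far = np.where(dz > 0, (z_d - pos[flying, 2]) / dz, np.inf)
                s_near = np.where(dz < 0, -pos[flying, 2] / dz, np.inf)
            s_cross = np.maximum(np.minimum(s_far, s_near), 0.0)
            crossing = s_cross < rem

            inside = flying[~crossing]
            pos[inside] += dirs[inside] * rem[~crossing][:, None]
            path[inside] += rem[~crossing]

            cross = flying[crossing]
            if cross.size == 0:
                flying = np.zeros(0, dtype=int)
                break
            sc = s_cross[crossing]
            pos[cross] += dirs[cross] * sc[:, None]
            path[cross] += sc
            remaining[cross] = rem[crossing] - sc
            cos_i = np.abs(dirs[cross, 2])
            if fresnel:
                reflected = rng.random(cross.size) < _fresnel_reflectance(cos_i, n_medium)
            else:
                reflected = np.zeros(cross.size, dtype=bool)

            esc = cross[~reflected]
            far = esc[dirs[esc, 2] > 0]
            out_t.append(path[far] / c)
            out_w.append(np.exp(-mu_a * path[far]))
            out_r.append(np.hypot(pos[far, 0], pos[far, 1]))
            alive[esc] = False

            refl = cross[reflected]
            dirs[refl, 2] = -dirs[refl, 2]
            pos[refl, 2] = np.clip(pos[refl, 2], 1e-12, z_d - 1e-12)
            flying = refl
        else:
            # bounce budget exhausted: drop the stragglers (negligible weight)
            alive[flying] = False

        live = np.nonzero(alive)[0]
        cosz = rng.uniform(-1.0, 1.0, size=live.size)
        phi = rng.uniform(0.0, 2 * np.pi, size=live.size)
        sinz = np.sqrt(1.0 - cosz**2)
        dirs[live, 0] = sinz * np.cos(phi)
        dirs[live, 1] = sinz * np.sin(phi)
        dirs[live, 2] = cosz

    if out_t:
        return (np.concatenate(out_t), np.concatenate(out_w), np.concatenate(out_r))
    return np.zeros(0), np.zeros(0), np.zeros(0)


def mc_transmittance_histogram(
    mu_a: float,
    mu_s_prime: float,
    n_medium: float,
    z_d: float,
    n_photons: int,
    seed: int,
    t_edges: np.ndarray,
    **kwargs,
) -> np.ndarray:
    """Plane-integrated transmitted-power histogram over ``t_edges`` (ns)."""
    t, w, _ = mc_transmitted_photons(mu_a, mu_s_prime, n_medium, z_d,
                                     n_photons, seed, **kwargs)
    hist, _ = np.histogram(t, bins=t_edges, weights=w)
    return hist
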