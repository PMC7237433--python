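"""Independent oracles used by several test modules.

These deliberately re-derive the quantities they check through different
routes (Monte-Carlo ray averaging, extended-precision normal equations)
and never call the implementation under test.
"""

import numpy as np


def mc_slab_attenuation(mu_s, mu_c, d_s, d_c, tilt_deg, two_theta_deg,
                        scatter_in, attenuate, n_rays=200_000, seed=0):
    """Monte-Carlo ray average of the slab attenuation factor.

    Scattering depths are sampled uniformly over the requested region
    (``scatter_in`` = 'sample' or 'container'); ``attenuate`` lists the
    layers whose attenuation applies ('s', 'c').  The slab normal makes
    ``tilt_deg`` with the beam; the exit ray leaves at ``two_theta_deg``
    in the plane containing beam and normal.  Container walls of
    thickness d_c/2 sit on both sides of the sample.
    """
    rng = np.random.default_rng(seed)
    w = d_c / 2.0
    if scatter_in == "sample":
        t = w + rng.random(n_rays) * d_s
    else:
        u = rng.random(n_rays) * d_c
        t = np.where(u < w, u, u + d_s)  # front wall or back wall
    cos_in = np.cos(np.radians(tilt_deg))
    cos_out = np.cos(np.radians(two_theta_deg - tilt_deg))
    total = 2 * w + d_s

    c_front = np.minimum(t, w) + np.maximum(0.0, t - w - d_s)
    s_front = np.clip(t - w, 0.0, d_s)
    c_back = np.maximum(0.0, w - t) + np.minimum(w, total - np.maximum(t, w + d_s))
    s_back = d_s - s_front
    if cos_out > 0:
        c_out, s_out = c_back, s_back
    else:
        c_out, s_out = c_front, s_front

    mu_s_eff = mu_s if "s" in attenuate else 0.0
    mu_c_eff = mu_c if "c" in attenuate else 0.0
    path = ((mu_c_eff * c_front + mu_s_eff * s_front) / cos_in
            + (mu_c_eff * c_out + mu_s_eff * s_out) / abs(cos_out))
    return float(np.mean(np.exp(-path)))


def longdouble_wls_line(x, y, sigma):
    """Weighted least-squares line by normal equations in extended precision."""
    x = np.asarray(x, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    w = 1.0 / np.asarray(sigma, dtype=np.longdouble) ** 2
    S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    return float(slope), float(intercept)
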