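"""Independent reference computations used by the test suite.

These deliberately avoid the implementation's numerical shortcuts: the dose
oracle is a direct Cartesian double-sum 2-D convolution (no radial symmetry,
no Bessel identities), and the disc-average oracle is a closed form.
"""

import numpy as np

from srscone.synthetic_field import DEFAULT_SEED, _spot_samples, terma_depth_factor


def brute_force_fluence_grid(beam, cone, z, step=0.1, n_spot=600, seed=DEFAULT_SEED,
                             chunk=20000):
    """(x, y, fluence) on a Cartesian grid covering the fluence support."""
    sx, sy = _spot_samples(beam.focal_spot_diameter / 2.0, n_spot, seed)
    spot_r = beam.focal_spot_diameter / 2.0
    redge = min(-spot_r + (ra + spot_r) * z / za for ra, za in cone.apertures) + step
    xs = np.arange(-redge, redge + step / 2.0, step)
    X, Y = np.meshgrid(xs, xs)
    mask = X ** 2 + Y ** 2 <= redge ** 2
    Xf, Yf = X[mask], Y[mask]
    F = np.empty(Xf.size)
    for lo in range(0, Xf.size, chunk):
        hi = min(lo + chunk, Xf.size)
        vis = np.ones((hi - lo, sx.size), dtype=bool)
        for ra, za in cone.apertures:
            t = za / z
            qx = sx[None, :] + (Xf[lo:hi, None] - sx[None, :]) * t
            qy = sy[None, :] + (Yf[lo:hi, None] - sy[None, :]) * t
            vis &= qx * qx + qy * qy <= ra * ra
        F[lo:hi] = vis.mean(axis=1)
    return Xf, Yf, F, step


def brute_force_dose(beam, cone, grid, r0, z, depth):
    """Direct double-sum convolution of the fluence grid with the kernel."""
    Xf, Yf, F, step = grid
    total = 0.0
    for w, sig in beam.kernel_components:
        d2 = (Xf - r0) ** 2 + Yf ** 2
        total += (
            w
            * np.sum(F * np.exp(-d2 / (2.0 * sig * sig)))
            / (2.0 * np.pi * sig * sig)
            * step
            * step
        )
    return (
        beam.output_normalization
        * terma_depth_factor(beam, depth, z)
        * total
    )


def gaussian_disc_average(sigma, radius):
    """Mean of exp(-r^2/2 sigma^2) over a centred disc (closed form)."""
    x = radius ** 2 / (2.0 * sigma ** 2)
    return (1.0 - np.exp(-x)) / x


def mc_sigma_product(a, sa, b, sb, n=100_000, seed=0, ratio=False):
    """Monte-Carlo 1-sigma of a*b or a/b for independent Gaussian inputs."""
    rng = np.random.default_rng(seed)
    xa = rng.normal(a, sa, n)
    xb = rng.normal(b, sb, n)
    vals = xa / xb if ratio else xa * xb
    return float(vals.std(ddof=1))
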