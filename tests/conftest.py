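import numpy as np
import pytest

from soxoct import binding


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sox_only_params():
    """Sox2-only binding on the Fgf4 element (Kd from the measured aKd)."""
    return binding.BindingParameters(kd_sox=70.2, kd_oct=42.5, omega=1.0)


def single_site_bound_fraction(p_total, d_total, kd):
    """Closed-form depletion quadratic for one protein, one site.

    Independent oracle: fraction of DNA bound,
    f = ((P + D + K) - sqrt((P + D + K)^2 - 4 P D)) / (2 D).
    """
    s = p_total + d_total + kd
    return (s - np.sqrt(s * s - 4.0 * p_total * d_total)) / (2.0 * d_total)


def fixed_point_equilibrium(kd_sox, kd_oct, omega, d_tot, s_tot, o_tot,
                            tol=1e-12, max_iter=200000):
    """Brute-force fixed-point iteration oracle for the two-site equilibrium.

    Damped Picard iteration on the free monomer concentrations; slow but
    entirely independent of the package's bracketed root solver.
    """
    s, o = s_tot, o_tot
    for _ in range(max_iter):
        zs, zo = s / kd_sox, o / kd_oct
        zt = omega * zs * zo
        z = 1.0 + zs + zo + zt
        fd = d_tot / z
        s_new = s_tot - fd * (zs + zt)
        o_new = o_tot - fd * (zo + zt)
        s_next = 0.5 * s + 0.5 * max(s_new, 0.0)
        o_next = 0.5 * o + 0.5 * max(o_new, 0.0)
        if abs(s_next - s) < tol * max(s_tot, 1.0) and abs(o_next - o) < tol * max(o_tot, 1.0):
            return s_next, o_next
        s, o = s_next, o_next
    raise RuntimeError("fixed-point oracle did not converge")
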