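"""Independent reference implementations used only to check production code.

The step-wise propagator here uses scipy.linalg.expm and an explicit
per-echo loop with complex conjugation at each 180-degree pulse — a
deliberately different code path from the batched eigendecomposition and
closed-form matrix power used by the package.
"""

import numpy as np
from scipy.linalg import expm


def stepwise_bm_r2eff(k_ex, p_B, dw_ppm, r20, larmor_mhz, t_relax, nu):
    """R2,eff by brute-force echo-by-echo Bloch-McConnell propagation."""
    p_A = 1.0 - p_B
    k_AB, k_BA = p_B * k_ex, p_A * k_ex
    dw = dw_ppm * 2.0 * np.pi * larmor_mhz
    L = np.array(
        [[-r20 - k_AB, k_BA], [k_AB, -r20 - k_BA - 1j * dw]], dtype=complex
    )
    n = int(round(t_relax * 2.0 * nu))
    n += n % 2
    n = max(n, 2)
    tau = t_relax / (2.0 * n)
    P = expm(L * tau)
    M = np.array([p_A, p_B], dtype=complex)
    for _ in range(n):
        M = P @ np.conj(P @ M)  # delay - 180 (conjugation) - delay
    return -np.log(abs(M[0]) / p_A) / t_relax
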