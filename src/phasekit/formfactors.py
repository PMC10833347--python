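"""X-ray scattering factors: 4-Gaussian + constant parameterisation.

Coefficients are the standard International Tables Vol. C (IT92) values,
f(s) = sum_i a_i exp(-b_i s^2) + c with s = sin(theta)/lambda = 1/(2d).
Only the elements needed for protein work plus a generic heavy atom are
bundled; ``HV`` (mercury coefficients) stands in for any unspecified heavy
scatterer in substructure site lists.
"""

from __future__ import annotations

import numpy as np

# element -> (a[4], b[4], c)
FORM_FACTORS: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.493002, 0.322912, 0.140191, 0.040810),
          (10.5109, 26.1257, 3.14236, 57.7997), 0.003038),
    "C": ((2.31, 1.02, 1.5886, 0.865),
          (20.8439, 10.2075, 0.5687, 51.6512), 0.2156),
    "N": ((12.2126, 3.1322, 2.0125, 1.1663),
          (0.0057, 9.8933, 28.9975, 0.5826), -11.529),
    "O": ((3.0485, 2.2868, 1.5463, 0.867),
          (13.2771, 5.7011, 0.3239, 32.9089), 0.2508),
    "S": ((6.9053, 5.2034, 1.4379, 1.5863),
          (1.4679, 22.2151, 0.2536, 56.172), 0.8669),
    "SE": ((17.0006, 5.8196, 3.9731, 4.3543),
           (2.4098, 0.2726, 15.2372, 43.8163), 2.8409),
    # generic heavy atom (Hg coefficients)
    "HV": ((20.6809, 19.0417, 21.6575, 5.9676),
           (0.545, 8.4484, 1.5729, 38.3246), 12.6089),
}


def normalize_element(element: str) -> str:
    el = element.strip().upper()
    if el in FORM_FACTORS:
        return el
    raise KeyError(
        f"no scattering entry for element {element!r}; "
        f"known: {sorted(FORM_FACTORS)}"
    )


def scattering_factor(element: str, s2: np.ndarray) -> np.ndarray:
    """f(s) for s^2 = (sin(theta)/lambda)^2 = 1/(4 d^2), vectorised."""
    a, b, c = FORM_FACTORS[normalize_element(element)]
    s2 = np.asarray(s2, dtype=float)
    f = np.full_like(s2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f
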