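"""Genetic map functions.

Converts between map distance (cM) and recombination fraction for the two
classical no-interference / interference models. Haldane is the package
default everywhere; Kosambi is available by name.
"""

from __future__ import annotations

import numpy as np

__all__ = ["haldane_r", "haldane_cm", "kosambi_r", "kosambi_cm", "get_map_function"]


def haldane_r(d_cm):
    """Recombination fraction for a map distance under Haldane's model.

    r = (1 - exp(-2d)) / 2 with d in Morgans; no crossover interference.
    """
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def haldane_cm(r):
    """Inverse Haldane map function: d(cM) = -50 * ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return -50.0 * np.log1p(-2.0 * r)


def kosambi_r(d_cm):
    """Recombination fraction under Kosambi's map function (partial interference)."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


def kosambi_cm(r):
    """Inverse Kosambi map function: d(cM) = 25 * ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAP_FUNCTIONS = {
    "haldane": (haldane_r, haldane_cm),
    "kosambi": (kosambi_r, kosambi_cm),
}


def get_map_function(name: str):
    """Return the (cM -> r, r -> cM) pair for a named map function."""
    try:
        return _MAP_FUNCTIONS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown map function {name!r}; choose from {sorted(_MAP_FUNCTIONS)}"
        ) from None
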