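"""Small deterministic optimisers used by the profiled fits."""

from __future__ import annotations

import math

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def golden_section_min(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Minimise a unimodal ``f`` on [lo, hi] to within ``tol`` on x.

    Ties are broken toward smaller x (the left bracket is kept on equality),
    so repeated runs are bit-reproducible.  Returns (x*, f(x*)).
    """
    a, b = float(lo), float(hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    x = c if fc <= fd else d
    return (x, min(fc, fd))
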