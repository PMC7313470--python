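import itertools

import numpy as np
import pytest

from retinamech.fem.stretcher import StretcherModel
from retinamech.synthetic import RegimeParams


@pytest.fixture(scope="session")
def stretcher_res1():
    return StretcherModel(resolution=1)


@pytest.fixture(scope="session")
def stretcher_res2():
    return StretcherModel(resolution=2)


@pytest.fixture(scope="session")
def stretcher_default():
    """Stretcher at the production resolution (level 4)."""
    return StretcherModel()


@pytest.fixture(scope="session")
def short_record_params():
    """Regime parameters for a 0.5 mm record where all five pieces remain
    resolvable on curves short enough for exhaustive breakpoint search."""
    return RegimeParams(
        rate=2e-6, toe_end=1e-5, k1=21.5, F_y1=1.5e-3,
        plateau2_len=2e-4, k3=43.0, F_y2=3.75e-3, d_max=5e-4,
    )


def exhaustive_regime_sse(d, f, n_breakpoints, min_pts, plateau_frac=0.1):
    """Brute-force oracle: global minimum of the continuous piecewise-linear
    SSE over *all* admissible breakpoint tuples on the sample grid.

    Independent of the package's search: plain lstsq per candidate, with the
    same structural admissibility rule (positive rising slopes, plateau
    slopes bounded by ``plateau_frac`` of the preceding rise).
    """
    n = len(d)
    xs = d / d[-1]
    yscale = np.max(np.abs(f))
    ys = f / yscale
    best = np.inf
    best_combo = None
    for combo in itertools.combinations(range(min_pts, n - min_pts), n_breakpoints):
        if any(combo[i + 1] - combo[i] < min_pts for i in range(n_breakpoints - 1)):
            continue
        edges = np.concatenate(([xs[0]], xs[list(combo)], [xs[-1]]))
        cols = [np.ones_like(xs)]
        for j in range(len(edges) - 1):
            cols.append(np.clip(xs - edges[j], 0.0, edges[j + 1] - edges[j]))
        X = np.stack(cols, axis=1)
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        s = beta[1:]
        if n_breakpoints == 4 and not (
            s[1] > 0 and abs(s[2]) <= plateau_frac * s[1]
            and s[3] > 0 and abs(s[4]) <= plateau_frac * s[3]
        ):
            continue
        r = ys - X @ beta
        sse = float(r @ r)
        if sse < best:
            best, best_combo = sse, combo
    return best * yscale**2, best_combo
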