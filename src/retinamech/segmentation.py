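"""Segmentation of FD curves into toe + four deformation regimes.

A stretched retina shows a characteristic force-distance shape: a short
nonlinear toe (< 0.01 mm, loose clamping and entropic network effects), a
linear elastic rise (regime 1), a constant-force plateau after the first
yield (regime 2), a second, steeper linear rise (regime 3) and a second
plateau (regime 4).  This module fits a *continuous* piecewise-linear model
with four breakpoints to one curve by least squares: the toe/regime-1
boundary is initialised at the 0.01 mm toe end, the remaining breakpoints
by an exhaustive typed dynamic program (lines for rising regimes, constants
for plateaus) over the sample grid, and the tuple is then refined by
coordinate descent of the continuous-model SSE, accepting only
configurations whose fitted slopes respect the regime structure.  The fit
then extracts the mechanical parameters:

* ``k1``, ``k3``: slopes of regimes 1 and 3 [N/m] ("elastic constants" in
  the structural, not material, sense), refit by OLS on the interior samples
  of each linear regime (samples below the 0.01 mm toe cutoff are excluded
  from the regime-1 fit);
* ``F_y1``, ``F_y2``: yield forces, the maximum measured force within a few
  samples of the regime 1->2 and 3->4 transitions;
* plateau forces: mean force over the interiors of regimes 2 and 4.

Replicate fits at one displacement rate are summarised as mean +/- SD.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import lsq_linear

from .curves import FDCurve

__all__ = [
    "SegmentationError",
    "SegmentationOptions",
    "RegimeFit",
    "ReplicateSummary",
    "RegimeModel",
    "segment_regimes",
    "summarize_replicates",
]

_PIECE_NAMES = ("toe", "regime1", "plateau2", "regime3", "plateau4")


class SegmentationError(RuntimeError):
    """Raised when a curve cannot be decomposed into the requested regimes."""


@dataclass(frozen=True)
class SegmentationOptions:
    """Settings for :class:`RegimeModel`.

    ``n_breakpoints`` is 4 for a full curve; partial curves (experiments
    stopped inside an earlier regime) can be fit with fewer pieces, in which
    case only the parameters of the regimes actually present are reported
    and the fit is flagged ``partial``.
    """

    n_breakpoints: int = 4
    min_seg_points: int = 5          # minimum samples per piece
    toe_init: float = 1.0e-5         # [m] initial toe/regime-1 boundary (0.01 mm)
    refine_window: int = 12          # +/- samples scanned per breakpoint per pass
    max_refine_passes: int = 30
    smooth_window: int | None = None  # odd moving-average width; None = off
    toe_exclusion: float = 1.0e-5    # [m] samples below this excluded from k1 refit
    yield_window: int = 5            # +/- samples around a breakpoint for yield force
    edge_margin: int = 2             # samples dropped next to breakpoints in refits
    plateau_slope_frac: float = 0.1  # |plateau slope| <= frac * preceding line slope
    enforce_k3_gt_k1: bool = False

    def __post_init__(self):
        if not 1 <= self.n_breakpoints <= 4:
            raise ValueError("n_breakpoints must be between 1 and 4")
        if self.min_seg_points < 2:
            raise ValueError("min_seg_points must be at least 2")
        if self.smooth_window is not None and (
            self.smooth_window < 3 or self.smooth_window % 2 == 0
        ):
            raise ValueError("smooth_window must be odd and >= 3")


@dataclass(frozen=True)
class RegimeFit:
    """Results object of :class:`RegimeModel`.

    ``breakpoints`` are the fitted transition displacements [m] in order
    toe->1, 1->2, 2->3, 3->4 (shorter for partial fits).  ``slopes`` are the
    raw piecewise-model slopes; ``k1``/``k3`` are the interior OLS refits
    reported as the elastic constants.
    """

    breakpoints: tuple
    breakpoint_indices: tuple
    slopes: tuple
    k1: float | None
    k3: float | None
    F_y1: float | None
    F_y2: float | None
    plateau_forces: tuple
    sse: float
    rate: float
    n_points: int
    partial: bool = False
    no_yield_detected: bool = False
    options: SegmentationOptions = field(default_factory=SegmentationOptions)

    def summary(self) -> str:
        bp = ", ".join(f"{b * 1e6:.1f}" for b in self.breakpoints)
        lines = [
            "FD-curve regime segmentation (continuous piecewise-linear LSQ)",
            f"  samples          : {self.n_points}",
            f"  rate             : {self.rate * 1e6:.2f} um/s",
            f"  breakpoints [um] : {bp}",
        ]
        if self.k1 is not None:
            lines.append(f"  k1 (regime 1)    : {self.k1:.3f} N/m")
        if self.F_y1 is not None:
            lines.append(f"  F_y1             : {self.F_y1 * 1e3:.3f} mN")
        if self.k3 is not None:
            lines.append(f"  k3 (regime 3)    : {self.k3:.3f} N/m")
        if self.F_y2 is not None:
            lines.append(f"  F_y2             : {self.F_y2 * 1e3:.3f} mN")
        lines.append(f"  SSE              : {self.sse:.3e} N^2")
        if self.partial:
            lines.append("  NOTE: partial curve, reduced regime model")
        if self.no_yield_detected:
            lines.append("  WARNING: no yield plateau detected")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "breakpoints_m": list(self.breakpoints),
            "slopes_N_per_m": list(self.slopes),
            "k1_N_per_m": self.k1,
            "k3_N_per_m": self.k3,
            "F_y1_N": self.F_y1,
            "F_y2_N": self.F_y2,
            "plateau_forces_N": list(self.plateau_forces),
            "sse_N2": self.sse,
            "rate_m_per_s": self.rate,
            "n_points": self.n_points,
            "partial": self.partial,
            "no_yield_detected": self.no_yield_detected,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def plot(self, curve: FDCurve, ax=None):
        """Diagnostic plot: data, fitted piecewise model and breakpoints."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d, f = curve.displacement, curve.force
        ax.plot(d * 1e3, f * 1e3, ".", ms=2, color="0.6", label="data")
        edges = np.concatenate(([d[0]], self.breakpoints, [d[-1]]))
        # reconstruct the continuous piecewise model from its slopes
        xs, ys = [edges[0]], [0.0]
        level = 0.0
        for j, s in enumerate(self.slopes):
            level += s * (edges[j + 1] - edges[j])
            xs.append(edges[j + 1])
            ys.append(level)
        ax.plot(np.array(xs) * 1e3, np.array(ys) * 1e3, "-", color="C3", label="piecewise fit")
        for b in self.breakpoints:
            ax.axvline(b * 1e3, color="C0", lw=0.5, ls="--")
        ax.set_xlabel("displacement [mm]")
        ax.set_ylabel("force [mN]")
        ax.legend()
        return ax


# --------------------------------------------------------------------------
# piecewise-linear machinery
# --------------------------------------------------------------------------

def _design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix of the continuous piecewise-linear model.

    Columns: intercept, then one per piece whose entry is the length of that
    piece's interval covered up to x; the coefficient of each column is the
    slope of that piece, so continuity is built in and per-piece slope bounds
    become simple box constraints.
    """
    edges = np.concatenate(([x[0]], knots, [x[-1]]))
    cols = [np.ones_like(x)]
    for j in range(len(edges) - 1):
        cols.append(np.clip(x - edges[j], 0.0, edges[j + 1] - edges[j]))
    return np.stack(cols, axis=1)


def _fit_at(x: np.ndarray, y: np.ndarray, idx: tuple) -> tuple[float, np.ndarray]:
    """SSE and coefficients of the continuous piecewise fit with breakpoints
    at sample indices ``idx`` (solved via normal equations; x, y are assumed
    pre-scaled to O(1))."""
    X = _design_matrix(x, x[list(idx)])
    G = X.T @ X
    c = X.T @ y
    try:
        beta = np.linalg.solve(G, c)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _admissible(idx: tuple, n: int, min_pts: int) -> bool:
    prev = 0
    for i in idx:
        if i - prev < min_pts:
            return False
        prev = i
    return n - 1 - prev >= min_pts


def _slopes_valid(beta: np.ndarray, nb: int, frac: float, enforce_k3: bool) -> bool:
    """Structural validity of fitted piece slopes.

    Rising regimes must have positive slope; a plateau's slope magnitude
    must not exceed ``frac`` of the preceding rising regime's slope.  The
    constraints act on the scaled fit, which is equivalent (all scale
    factors are positive).
    """
    s = beta[1:]
    names = _PIECE_NAMES[: nb + 1]
    if "regime1" in names and not s[1] > 0:
        return False
    if "plateau2" in names and not abs(s[2]) <= frac * s[1]:
        return False
    if "regime3" in names and not s[3] > 0:
        return False
    if "plateau4" in names and not abs(s[4]) <= frac * s[3]:
        return False
    if enforce_k3 and "regime3" in names and not s[3] > s[1]:
        return False
    return True


def _segment_costs(x: np.ndarray, y: np.ndarray, min_pts: int):
    """Per-segment fit costs for all index pairs, from cumulative sums.

    Returns ``(C_line, C_const)`` where ``C_line[i, j]`` is the SSE of an
    independent OLS line on samples i..j inclusive and ``C_const[i, j]`` the
    SSE of a constant fit; segments shorter than ``min_pts`` are +inf.
    """
    n = x.size
    one = np.ones(n)
    cs = {name: np.concatenate(([0.0], np.cumsum(v)))
          for name, v in (("n", one), ("x", x), ("y", y),
                          ("xx", x * x), ("xy", x * y), ("yy", y * y))}
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]

    def seg(name):
        return cs[name][j + 1] - cs[name][i]

    m = seg("n")
    with np.errstate(divide="ignore", invalid="ignore"):
        sx, sy, sxx, sxy, syy = seg("x"), seg("y"), seg("xx"), seg("xy"), seg("yy")
        vxx = sxx - sx * sx / m
        vxy = sxy - sx * sy / m
        vyy = syy - sy * sy / m
        slope2 = np.where(vxx > 0, vxy * vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
        C_line = vyy - slope2
    valid = (j - i + 1 >= min_pts) & (j >= i)
    C_line = np.where(valid, np.maximum(C_line, 0.0), np.inf)
    C_const = np.where(valid, np.maximum(vyy, 0.0), np.inf)
    return C_line, C_const


def _typed_dp(x: np.ndarray, y: np.ndarray, types, min_pts: int) -> tuple:
    """Optimal breakpoints of the *discontinuous* typed piecewise fit.

    ``types`` is a sequence of ``"line"``/``"const"`` segment kinds in
    order.  Dynamic programming over per-segment OLS costs; linear regimes
    use free lines, constant-force plateaus use constant fits, which is
    what keeps the long final plateau from stealing a breakpoint to chase
    noise.  Returns the segment start indices (the breakpoints).
    """
    n = x.size
    C_line, C_const = _segment_costs(x, y, min_pts)
    cost_of = {"line": C_line, "const": C_const}
    n_seg = len(types)
    best = cost_of[types[0]][0, :].copy()  # cover 0..j with the first segment
    choice = np.zeros((n_seg, n), dtype=np.int64)
    for s in range(1, n_seg):
        # M[i-1, j] = best cost of 0..i-1 with s segments plus segment i..j
        M = best[:-1, None] + cost_of[types[s]][1:, :]
        M = np.where(np.isfinite(M), M, np.inf)
        arg = np.argmin(M, axis=0)
        best = M[arg, np.arange(n)]
        choice[s] = arg + 1  # start index of segment s
    if not np.isfinite(best[n - 1]):
        raise SegmentationError("no admissible segmentation (curve too short)")
    starts = []
    j = n - 1
    for s in range(n_seg - 1, 0, -1):
        i = int(choice[s, j])
        starts.append(i)
        j = i - 1
    starts.reverse()
    return tuple(starts)


def _coordinate_descent(x, y, idx, lo, hi, min_pts, window, max_passes, validate=None):
    """Local exhaustive refinement of the continuous-model SSE, one
    breakpoint at a time on the sample grid.

    With ``validate`` given, only structurally valid configurations are
    accepted; an invalid starting point has infinite cost, so the first
    valid neighbour (if any) is adopted.
    """
    nb = len(idx)
    idx = list(idx)
    best_sse, beta = _fit_at(x, y, tuple(idx))
    if validate is not None and not validate(beta):
        best_sse = np.inf
    for _ in range(max_passes):
        moved = False
        for k in range(nb):
            left = idx[k - 1] + min_pts if k > 0 else lo
            right = idx[k + 1] - min_pts if k < nb - 1 else hi - 1
            a = max(left, idx[k] - window)
            b = min(right, idx[k] + window)
            for j in range(a, b + 1):
                if j == idx[k]:
                    continue
                trial = tuple(idx[:k] + [j] + idx[k + 1:])
                sse, beta = _fit_at(x, y, trial)
                if sse < best_sse * (1 - 1e-14) - 1e-300 and (
                    validate is None or validate(beta)
                ):
                    best_sse = sse
                    idx[k] = j
                    moved = True
        if not moved:
            break
    return tuple(idx), best_sse


def _search_breakpoints(x, y, nb, min_pts, toe_idx, max_passes, window,
                        validate=None, dp_max_n=2000):
    """Breakpoint search for the continuous piecewise-linear model.

    Initialisation: the toe/regime-1 boundary starts at the known toe end
    (0.01 mm); the remaining breakpoints come from an exhaustive typed
    dynamic program (lines for the rising regimes, constants for the
    plateaus) over the samples beyond the toe.  The initial tuple is then
    refined by exhaustive coordinate descent of the continuous-model SSE on
    the full sample grid within a local window per breakpoint.  For long
    records the DP runs on a strided subsample (the refinement window covers
    the stride).
    """
    n = len(x)
    lo, hi = min_pts, n - min_pts  # candidate index range [lo, hi)
    if hi - lo < nb:
        raise SegmentationError("too few samples for the requested number of regimes")
    types = ["line" if _PIECE_NAMES[p] in ("toe", "regime1", "regime3") else "const"
             for p in range(nb + 1)]

    i0 = int(np.clip(toe_idx, lo, hi - 1 - (nb - 1) * min_pts))
    idx0 = [i0]
    stride = 1
    if nb > 1:
        sub = np.arange(i0, n)
        stride = max(1, int(np.ceil(sub.size / dp_max_n)))
        sub = sub[::stride]
        if sub.size < nb * min_pts + 1:
            raise SegmentationError("too few samples beyond the toe for the regimes")
        rel_min = max(2, min_pts // stride)
        starts = _typed_dp(x[sub], y[sub], types[1:], rel_min)
        idx0 += [int(sub[s]) for s in starts]
    idx0 = tuple(idx0)
    if not _admissible(idx0, n, min_pts):
        # push overlapping initial breakpoints apart
        fixed = list(idx0)
        for k in range(1, nb):
            fixed[k] = max(fixed[k], fixed[k - 1] + min_pts)
        fixed[-1] = min(fixed[-1], hi - 1)
        for k in range(nb - 2, -1, -1):
            fixed[k] = min(fixed[k], fixed[k + 1] - min_pts)
        idx0 = tuple(fixed)
        if not _admissible(idx0, n, min_pts):
            raise SegmentationError("could not place admissible initial breakpoints")

    w = max(window, stride + 2)
    return _coordinate_descent(x, y, idx0, lo, hi, min_pts, w, max_passes,
                               validate=validate)


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    pad = width // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


class RegimeModel:
    """Piecewise-linear regime model for one FD curve."""

    def __init__(self, curve: FDCurve, options: SegmentationOptions | None = None):
        self.curve = curve
        self.options = options or SegmentationOptions()

    def fit(self) -> RegimeFit:
        opts = self.options
        d = self.curve.displacement
        f = self.curve.force
        n = d.size
        nb = opts.n_breakpoints
        if n < (nb + 1) * opts.min_seg_points + 2:
            raise SegmentationError(
                f"{n} samples cannot hold {nb + 1} segments of >= {opts.min_seg_points} points"
            )
        if opts.smooth_window is not None:
            f = _moving_average(f, opts.smooth_window)

        # scale to O(1) for well-conditioned normal equations
        xs = d / d[-1]
        yscale = max(np.max(np.abs(f)), 1e-30)
        ys = f / yscale

        toe_idx = int(np.searchsorted(d, opts.toe_init))
        validate = lambda beta: _slopes_valid(  # noqa: E731
            beta, nb, opts.plateau_slope_frac, opts.enforce_k3_gt_k1
        )
        idx, sse_s = _search_breakpoints(
            xs, ys, nb, opts.min_seg_points, toe_idx,
            opts.max_refine_passes, opts.refine_window, validate=validate,
        )
        no_yield = False
        if not np.isfinite(sse_s):
            # no structurally valid configuration (e.g. a plateau-free curve):
            # fall back to the unrestricted fit and clamp the plateau slopes
            no_yield = True
            idx, sse_s = _search_breakpoints(
                xs, ys, nb, opts.min_seg_points, toe_idx,
                opts.max_refine_passes, opts.refine_window,
            )
        _, beta = _fit_at(xs, ys, idx)
        slopes = beta[1:] * yscale / d[-1]  # back to N/m
        sse = sse_s * yscale**2
        if no_yield:
            slopes = self._clamp_slopes(xs, ys, idx, slopes, yscale, d[-1])

        return self._extract(d, f, idx, slopes, sse, no_yield)

    # ------------------------------------------------------------------
    def _clamp_slopes(self, xs, ys, idx, slopes, yscale, xscale):
        """Bounded refit for curves with no structurally valid configuration.

        Used only on the fallback path (``no_yield_detected``): line slopes
        are forced non-negative and plateau slopes are boxed at
        ``plateau_slope_frac`` of the preceding line's unconstrained slope,
        so downstream consumers still see a structurally shaped fit.
        """
        opts = self.options
        nb = len(idx)
        line_pos = [i for i in range(nb + 1) if _PIECE_NAMES[i] in ("regime1", "regime3")]
        plat_pos = [i for i in range(nb + 1) if _PIECE_NAMES[i] in ("plateau2", "plateau4")]

        sc = yscale / xscale
        lo = np.full(nb + 2, -np.inf)
        hi = np.full(nb + 2, np.inf)
        span = max(ys.max() - ys.min(), 1e-12)  # scaled fallback slope scale
        for i in line_pos:
            lo[i + 1] = 1e-9 * span
        for p in plat_pos:
            ref = max(abs(slopes[p - 1]) / sc, 1e-3 * span)
            lo[p + 1] = -opts.plateau_slope_frac * ref
            hi[p + 1] = opts.plateau_slope_frac * ref
        X = _design_matrix(xs, xs[list(idx)])
        res = lsq_linear(X, ys, bounds=(lo, hi))
        return tuple(res.x[1:] * sc)

    # ------------------------------------------------------------------
    def _extract(self, d, f, idx, slopes, sse, no_yield) -> RegimeFit:
        opts = self.options
        n = d.size
        nb = len(idx)
        pieces = _PIECE_NAMES[: nb + 1]
        bounds = [0, *idx, n - 1]  # sample-index edges of the pieces
        m = opts.edge_margin

        def interior(piece_no, extra_lo=0.0):
            a, b = bounds[piece_no] + m, bounds[piece_no + 1] - m
            sel = np.arange(max(a, 0), min(b, n - 1) + 1)
            if extra_lo > 0:
                sel = sel[d[sel] >= extra_lo]
            return sel

        def ols_slope(sel, fallback):
            if sel.size < 2:
                return float(fallback)
            return float(np.polyfit(d[sel], f[sel], 1)[0])

        k1 = k3 = F_y1 = F_y2 = None
        plateaus = []
        if "regime1" in pieces:
            k1 = ols_slope(interior(1, extra_lo=opts.toe_exclusion), slopes[1])
        if "regime3" in pieces:
            k3 = ols_slope(interior(3), slopes[3])
        if "plateau2" in pieces:
            w = opts.yield_window
            F_y1 = float(np.max(f[max(idx[1] - w, 0): min(idx[1] + w, n - 1) + 1]))
            sel = interior(2)
            plateaus.append(float(np.mean(f[sel])) if sel.size else F_y1)
        if "plateau4" in pieces:
            w = opts.yield_window
            F_y2 = float(np.max(f[max(idx[3] - w, 0): min(idx[3] + w, n - 1) + 1]))
            sel = interior(4)
            plateaus.append(float(np.mean(f[sel])) if sel.size else F_y2)

        return RegimeFit(
            breakpoints=tuple(float(d[i]) for i in idx),
            breakpoint_indices=tuple(int(i) for i in idx),
            slopes=tuple(float(s) for s in slopes),
            k1=k1,
            k3=k3,
            F_y1=F_y1,
            F_y2=F_y2,
            plateau_forces=tuple(plateaus),
            sse=float(sse),
            rate=self.curve.rate,
            n_points=n,
            partial=nb < 4,
            no_yield_detected=no_yield,
            options=opts,
        )


def segment_regimes(curve: FDCurve, options: SegmentationOptions | None = None) -> RegimeFit:
    """Segment one FD curve into toe + regimes and extract its parameters."""
    return RegimeModel(curve, options).fit()


# --------------------------------------------------------------------------
# replicate summaries
# --------------------------------------------------------------------------

_SUMMARY_PARAMS = ("k1", "k3", "F_y1", "F_y2")


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and SD of the regime parameters across replicate curves at one rate.

    SD is the sample standard deviation (n-1 denominator); 0 for n = 1.
    """

    rate: float
    n: int
    stats: dict  # name -> (mean, sd)

    def summary(self) -> str:
        lines = [f"Replicate summary at {self.rate * 1e6:.2f} um/s (n = {self.n})"]
        for name, (mean, sd) in self.stats.items():
            unit = "N/m" if name.startswith("k") else "N"
            lines.append(f"  {name:5s}: {mean:.4g} +/- {sd:.3g} {unit}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "rate_m_per_s": self.rate,
            "n": self.n,
            **{name: {"mean": mu, "sd": sd} for name, (mu, sd) in self.stats.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def summarize_replicates(fits, rate: float | None = None) -> ReplicateSummary:
    """Mean +/- SD of k1, k3, F_y1, F_y2 over replicate fits at one rate."""
    fits = list(fits)
    if not fits:
        raise ValueError("summarize_replicates needs at least one fit")
    rates = {f.rate for f in fits}
    if rate is None:
        if len(rates) > 1:
            raise ValueError(f"fits mix displacement rates: {sorted(rates)}")
        rate = fits[0].rate
    elif any(abs(r - rate) > 1e-12 * max(rate, 1e-30) for r in rates):
        raise ValueError("fits do not all match the requested rate")

    stats = {}
    for name in _SUMMARY_PARAMS:
        vals = np.array([getattr(f, name) for f in fits if getattr(f, name) is not None],
                        dtype=float)
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        stats[name] = (float(np.mean(vals)), sd)
    return ReplicateSummary(rate=float(rate), n=len(fits), stats=stats)
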