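"""Bimodal spacing distributions and the belt-geometry consistency check.

Ligand–ligand center distances measured from micrographs form a bimodal
distribution: a dominant population of closely spaced pairs and a minor
widely spaced one.  A k-component normal mixture is fit by
expectation-maximization on the raw distances (no histogram binning), the
major mode is the largest-weight component, and the wild-type vs mutant
major-mode difference is compared — with a bootstrap confidence interval —
against the arc length inserted into the belt between the two binding
sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .belt_model import BeltModel

__all__ = [
    "MixtureFit",
    "ModeShift",
    "GeometryReport",
    "fit_bimodal",
    "compare_modes",
    "geometry_consistency",
]

#: Minimum component SD (Å); prevents variance collapse onto single points.
SD_FLOOR = 0.5


@dataclass
class MixtureFit:
    """A fitted k-component normal mixture over distances (Å)."""

    modes: np.ndarray  # component means, ascending
    weights: np.ndarray
    sds: np.ndarray
    n_samples: int
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_trace: np.ndarray = field(repr=False, default=None)
    samples: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive")

    @property
    def k(self) -> int:
        return len(self.modes)

    @property
    def major_index(self) -> int:
        """Largest-weight component; ties broken by smaller mean."""
        order = sorted(range(self.k), key=lambda i: (-self.weights[i], self.modes[i]))
        return order[0]

    @property
    def major_mode(self) -> float:
        return float(self.modes[self.major_index])

    @property
    def major_weight(self) -> float:
        return float(self.weights[self.major_index])


def _log_gauss(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (
        -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        - np.log(sd[None, :])
        - 0.5 * math.log(2.0 * math.pi)
    )


def _em(
    x: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    w: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p = _log_gauss(x, mu, sd) + np.log(w[None, :])
        m = log_p.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_p - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / nk.sum()
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), SD_FLOOR)
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * max(abs(ll), 1.0):
            converged = True
            break
        ll_prev = ll
    # final likelihood under the returned parameters
    log_p = _log_gauss(x, mu, sd) + np.log(w[None, :])
    m = log_p.max(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))).sum())
    trace.append(ll)
    return mu, sd, w, ll, converged, it, trace


def fit_bimodal(
    samples,
    k: int = 2,
    max_iter: int = 500,
    tol: float = 1e-8,
    restarts: int = 5,
    seed: int = 0,
    init: MixtureFit | None = None,
) -> MixtureFit:
    """Fit a k-component normal mixture to distances by EM.

    The first start is deterministic — means at evenly spaced percentiles
    (25th/75th for k=2), pooled SD, equal weights; further restarts draw k
    distinct samples as initial means from a seeded generator, and the best
    final likelihood wins.  Convergence: relative log-likelihood change
    ≤ ``tol``.  Component SDs are floored at ``SD_FLOOR`` so degenerate
    (all-equal) inputs collapse gracefully onto a single effective mode.
    ``init`` warm-starts a single EM run from an existing fit (used by the
    bootstrap).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 10 * k:
        raise ValueError(f"need at least {10 * k} samples for k={k}, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")

    starts = []
    if init is not None:
        starts.append((init.modes.copy(), init.sds.copy(), init.weights.copy()))
        restarts = 1
    else:
        qs = np.linspace(25, 75, k)
        mu0 = np.percentile(x, qs)
        sd0 = np.full(k, max(float(x.std()), SD_FLOOR))
        w0 = np.full(k, 1.0 / k)
        starts.append((mu0, sd0, w0))
        rng = np.random.default_rng(seed)
        for _ in range(max(restarts, 1) - 1):
            mu_r = rng.choice(x, size=k, replace=False) if len(np.unique(x)) >= k else mu0
            starts.append((np.sort(np.asarray(mu_r, dtype=float)), sd0.copy(), w0.copy()))

    best = None
    for mu0, sd0, w0 in starts:
        mu, sd, w, ll, conv, it, trace = _em(x, mu0, sd0, w0, max_iter, tol)
        if best is None or ll > best[3]:
            best = (mu, sd, w, ll, conv, it, trace)
    mu, sd, w, ll, conv, it, trace = best
    order = np.argsort(mu)
    return MixtureFit(
        modes=mu[order],
        weights=w[order],
        sds=sd[order],
        n_samples=len(x),
        log_likelihood=ll,
        converged=conv,
        n_iter=it,
        ll_trace=np.asarray(trace),
        samples=x,
    )


@dataclass
class ModeShift:
    """Major-mode difference (mut − wt) with a percentile bootstrap CI."""

    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot_deltas: np.ndarray = field(repr=False, default=None)


def compare_modes(
    fit_wt: MixtureFit,
    fit_mut: MixtureFit,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> ModeShift:
    """Difference of the two fits' major modes, with bootstrap uncertainty.

    Each bootstrap resample refits by a warm-started EM from the parent fit.
    Refuses unconverged inputs — a mode from a non-converged EM is not a
    mode.
    """
    for name, fit in (("wt", fit_wt), ("mut", fit_mut)):
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge; refusing to compare modes")
        if fit.samples is None:
            raise ValueError(f"{name} fit carries no samples; refit with fit_bimodal")
    delta = fit_mut.major_mode - fit_wt.major_mode
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        res_wt = rng.choice(fit_wt.samples, size=len(fit_wt.samples), replace=True)
        res_mut = rng.choice(fit_mut.samples, size=len(fit_mut.samples), replace=True)
        f_wt = fit_bimodal(res_wt, k=fit_wt.k, init=fit_wt)
        f_mut = fit_bimodal(res_mut, k=fit_mut.k, init=fit_mut)
        deltas[b] = f_mut.major_mode - f_wt.major_mode
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(deltas, [100 * alpha, 100 * (1 - alpha)])
    return ModeShift(delta=delta, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, boot_deltas=deltas)


@dataclass
class GeometryReport:
    """Observed vs belt-predicted spacing shift."""

    observed: float
    predicted: float
    discrepancy: float
    consistent: bool
    arc_shift: float


def geometry_consistency(
    delta_mode: float,
    delta_arc_sites: float,
    belt: BeltModel | None = None,
    radial_offset: float = 0.0,
    tolerance: float = 4.0,
) -> GeometryReport:
    """Compare an observed major-mode shift with the belt's geometric prediction.

    ``delta_arc_sites`` is the arc length inserted between the two binding
    sites (the circumference growth attributable to the duplicated segment).
    Without a belt the flat-belt limit is used: the predicted chord shift
    equals the inserted arc.  With a belt, the chord between the two site
    azimuths is evaluated before and after the insertion at radius
    ``belt.radius + radial_offset`` (site separation and circumference both
    grow by the inserted arc); curvature makes the predicted chord shift at
    most the arc shift at that radius.
    """
    if belt is None:
        predicted = delta_arc_sites
        arc_shift = delta_arc_sites
    else:
        from .belt_model import default_site_azimuths

        az_a, az_b = default_site_azimuths(belt)
        dtheta1 = abs((az_b - az_a + math.pi) % (2.0 * math.pi) - math.pi)
        r1 = belt.radius + radial_offset
        s_belt = dtheta1 * belt.radius  # site arc at belt radius
        c2 = belt.circumference + delta_arc_sites
        radius2 = c2 / (2.0 * math.pi)
        dtheta2 = (s_belt + delta_arc_sites) / radius2
        r2 = radius2 + radial_offset
        chord1 = 2.0 * r1 * math.sin(dtheta1 / 2.0)
        chord2 = 2.0 * r2 * math.sin(min(dtheta2, 2 * math.pi - dtheta2) / 2.0)
        predicted = chord2 - chord1
        arc_shift = r2 * dtheta2 - r1 * dtheta1
    disc = abs(delta_mode - predicted)
    return GeometryReport(
        observed=delta_mode,
        predicted=predicted,
        discrepancy=disc,
        consistent=disc <= tolerance,
        arc_shift=arc_shift,
    )
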