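"""Sign-constrained kinematic regression and phasor extraction.

The firing rate of each cell is modeled per movement direction as

    fr(t) = b + c_p·X(t) + c_v·Xdot(t) + c_a·Xddot(t)

on a single channel (head or body kinematics), with all three kinematic
coefficients constrained to share one sign (the regression is solved once
under a non-negative and once under a non-positive criterion; the branch with
the lower residual sum of squares wins). The bias ``b`` is unconstrained and
shared across the two directions of a condition. Coefficients are pruned by a
nonparametric segment bootstrap (95% confidence intervals; non-significant
coefficients set to zero and the model refit), then converted to
(sensitivity, phase) phasors at f = 1 Hz.

Implementation note: fits are solved on per-segment Gram matrices via an
eigen square-root and NNLS (intercept split into a positive/negative pair),
which makes the 2000-draw bootstrap cheap and handles the benign
position/acceleration collinearity of pure sinusoidal stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import nnls

from .phasor import coeffs_to_sensitivity_phase
from .rates import RateTrace, segment_directions
from .synthetic_data import Channel, ConditionStimulus, Direction, Modality

__all__ = [
    "DirectionCoefficients",
    "KinematicCoefficients",
    "ResponseVector",
    "fit_kinematic",
    "bootstrap_prune",
    "to_response_vector",
    "vaf",
]

_COEF_NAMES = ("c_p", "c_v", "c_a")


@dataclass
class DirectionCoefficients:
    """Kinematic coefficient triple for one movement direction."""

    c_p: float = 0.0  # (sp/s)/deg
    c_v: float = 0.0  # (sp/s)/(deg/s)
    c_a: float = 0.0  # (sp/s)/(deg/s^2)
    ci_95: dict[str, tuple[float, float]] | None = None
    significant: dict[str, bool] | None = None
    present: bool = True

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.c_p, self.c_v, self.c_a)


@dataclass
class KinematicCoefficients:
    """Full per-condition fit: shared bias, per-direction triples, VAF."""

    b: float
    channel: Channel
    directions: dict[Direction, DirectionCoefficients]
    vaf: float
    rss: float
    freq: float = 1.0
    modality: Modality = Modality.VESTIBULAR

    def direction(self, d: Direction | str) -> DirectionCoefficients:
        return self.directions[Direction(d)]


@dataclass
class ResponseVector:
    """(sensitivity, phase) phasor of one direction's response at ``frequency``."""

    sensitivity: float  # (sp/s)/(deg/s), non-negative
    phase_deg: float  # (-180, 180]
    frequency: float = 1.0
    direction: Direction = Direction.IPSI
    modality: Modality = Modality.VESTIBULAR
    sign: int = 1  # +1 non-negative branch, -1 non-positive, 0 all-zero
    degenerate: bool = False  # all-zero coefficients: phase undefined

    @property
    def complex(self) -> complex:
        return self.sensitivity * np.exp(1j * np.radians(self.phase_deg))


# ---------------------------------------------------------------------------
# Gram-matrix machinery
# ---------------------------------------------------------------------------


@dataclass
class _SegmentGram:
    direction: Direction
    G3: np.ndarray  # (3,3) kinematics Gram
    g1: np.ndarray  # (3,) column sums (kinematics' inner product with 1)
    h3: np.ndarray  # (3,) kinematics' inner product with y
    ysum: float
    yy: float
    n: int


def _segment_grams(
    rate: np.ndarray, X: np.ndarray, segments_by_dir: dict[Direction, list]
) -> list[_SegmentGram]:
    grams = []
    for direction, segs in segments_by_dir.items():
        for seg in segs:
            A = X[seg.start : seg.stop]
            y = rate[seg.start : seg.stop]
            grams.append(
                _SegmentGram(
                    direction=direction,
                    G3=A.T @ A,
                    g1=A.sum(axis=0),
                    h3=A.T @ y,
                    ysum=float(y.sum()),
                    yy=float(y @ y),
                    n=len(y),
                )
            )
    return grams


def _assemble(grams: list[_SegmentGram], indices: np.ndarray | None = None):
    """Sum segment Grams into the 7x7 system [ipsi(3), contra(3), bias]."""
    G = np.zeros((7, 7))
    h = np.zeros(7)
    yy = 0.0
    ntot = 0
    chosen = grams if indices is None else [grams[i] for i in indices]
    for sg in chosen:
        off = 0 if sg.direction is Direction.IPSI else 3
        sl = slice(off, off + 3)
        G[sl, sl] += sg.G3
        G[sl, 6] += sg.g1
        G[6, sl] += sg.g1
        G[6, 6] += sg.n
        h[sl] += sg.h3
        h[6] += sg.ysum
        yy += sg.yy
        ntot += sg.n
    return G, h, yy, ntot


def _solve_branch(
    G: np.ndarray,
    h: np.ndarray,
    yy: float,
    sign_ipsi: int,
    sign_contra: int,
    active: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Solve the box-constrained LS for one sign-branch combination.

    ``active`` masks the six kinematic columns (pruned terms are excluded).
    Returns (kinematic coefficients (6,), bias, RSS).
    """
    signs = np.array([sign_ipsi] * 3 + [sign_contra] * 3, dtype=float)
    idx = np.flatnonzero(active)
    k = len(idx)
    # variable order: masked kinematics (sign-flipped to >=0), bias+, bias-
    d = signs[idx]
    Gk = G[np.ix_(np.r_[idx, 6], np.r_[idx, 6])].copy()
    flip = np.r_[d, 1.0]
    Gk = Gk * flip[:, None] * flip[None, :]
    hk = h[np.r_[idx, 6]] * flip
    # unit-diagonal column scaling for conditioning
    col = np.sqrt(np.clip(np.diag(Gk), 1e-300, None))
    Gk = Gk / col[:, None] / col[None, :]
    hk = hk / col
    # split the free bias into +/- parts
    M = np.zeros((k + 1, k + 2))
    M[:k, :k] = np.eye(k)
    M[k, k] = 1.0
    M[k, k + 1] = -1.0
    G8 = M.T @ Gk @ M
    h8 = M.T @ hk
    # tiny relative ridge: canonicalizes rank-deficient designs (pure
    # sinusoids make position/acceleration collinear) to the minimum-norm
    # point of the RSS-flat ridge without measurably biasing the fit
    ridge = 1e-11
    w, V = np.linalg.eigh(G8 + ridge * np.eye(k + 2))
    keep = w > 0
    if not np.any(keep):
        raise ValueError("degenerate design: all kinematic columns are zero")
    sqrt_w = np.sqrt(w[keep])
    A = sqrt_w[:, None] * V[:, keep].T
    bvec = (V[:, keep].T @ h8) / sqrt_w
    x, _ = nnls(A, bvec)
    rss = max(yy - 2.0 * h8 @ x + x @ G8 @ x, 0.0)
    coeffs = np.zeros(6)
    coeffs[idx] = d * x[:k] / col[:k]
    bias = (x[k] - x[k + 1]) / col[k]
    return coeffs, bias, rss


def _fit_from_grams(
    grams: list[_SegmentGram],
    indices: np.ndarray | None = None,
    active: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Enumerate sign branches per present direction; return the best fit."""
    G, h, yy, _ = _assemble(grams, indices)
    if active is None:
        active = np.ones(6, dtype=bool)
    have_ipsi = bool(np.any(np.abs(np.diag(G)[:3]) > 0) and np.any(active[:3]))
    have_contra = bool(np.any(np.abs(np.diag(G)[3:6]) > 0) and np.any(active[3:6]))
    act = active.copy()
    act[:3] &= have_ipsi
    act[3:6] &= have_contra
    ipsi_signs = (1, -1) if have_ipsi else (1,)
    contra_signs = (1, -1) if have_contra else (1,)
    best = None
    for si, sc in product(ipsi_signs, contra_signs):
        if not np.any(act):
            # intercept-only model
            n = G[6, 6]
            bias = h[6] / n if n > 0 else 0.0
            best = (np.zeros(6), bias, max(yy - n * bias**2, 0.0))
            break
        coeffs, bias, rss = _solve_branch(G, h, yy, si, sc, act)
        if best is None or rss < best[2] - 1e-12:
            best = (coeffs, bias, rss)
    assert best is not None
    return best


def _solve_unconstrained(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Minimum-norm OLS solution of the assembled normal equations.

    Used inside the bootstrap: the sign-constrained estimator folds at the
    zero boundary, so percentile intervals of constrained refits of a
    true-zero coefficient almost never cover zero. The unconstrained refit has
    the symmetric sampling distribution a percentile CI assumes.
    """
    return np.linalg.lstsq(G, h, rcond=None)[0]


def _predicted(rate, X, segments_by_dir, coeffs6, bias):
    """Fitted trace and observed values over all segment samples."""
    obs, fit = [], []
    for direction, segs in segments_by_dir.items():
        off = 0 if direction is Direction.IPSI else 3
        triple = coeffs6[off : off + 3]
        for seg in segs:
            obs.append(rate[seg.start : seg.stop])
            fit.append(bias + X[seg.start : seg.stop] @ triple)
    return np.concatenate(obs), np.concatenate(fit)


def _as_rate_array(rate: RateTrace | np.ndarray) -> np.ndarray:
    return rate.rate if isinstance(rate, RateTrace) else np.asarray(rate, dtype=float)


def _prepare(rate, stim: ConditionStimulus, channel):
    y = _as_rate_array(rate)
    channel = Channel(channel) if channel is not None else stim.driving_channel
    X = stim.trajectory(channel).kinematic_matrix()
    if len(y) != len(X):
        raise ValueError("rate and stimulus are on different grids")
    segs = segment_directions(stim)
    segs = {d: s for d, s in segs.items() if s}
    if sum(len(s) for s in segs.values()) < 1:
        raise ValueError("no movement segments to fit")
    # name degenerate channels early
    for d, slist in segs.items():
        block = np.concatenate([X[s.start : s.stop] for s in slist])
        if np.allclose(block, 0.0):
            raise ValueError(
                f"channel {channel.value!r} carries no kinematic signal in "
                f"{d.value} segments (collinear/degenerate design)"
            )
    return y, X, segs, channel


def _package(
    coeffs6, bias, rss, y, X, segs, channel, freq, modality,
    ci=None, signif=None,
) -> KinematicCoefficients:
    obs, fit = _predicted(y, X, segs, coeffs6, bias)
    directions = {}
    for d in Direction:
        off = 0 if d is Direction.IPSI else 3
        directions[d] = DirectionCoefficients(
            c_p=float(coeffs6[off]),
            c_v=float(coeffs6[off + 1]),
            c_a=float(coeffs6[off + 2]),
            ci_95=None if ci is None else ci.get(d),
            significant=None if signif is None else signif.get(d),
            present=d in segs,
        )
    return KinematicCoefficients(
        b=float(bias),
        channel=channel,
        directions=directions,
        vaf=vaf(obs, fit),
        rss=float(rss),
        freq=freq,
        modality=modality,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def fit_kinematic(
    rate: RateTrace | np.ndarray,
    stim: ConditionStimulus,
    channel: Channel | str | None = None,
    freq: float = 1.0,
    modality: Modality = Modality.VESTIBULAR,
) -> KinematicCoefficients:
    """Fit the sign-constrained kinematic regression for one condition.

    Both sign branches are solved per direction and the lower-RSS branch kept;
    the bias is shared across directions. ``channel`` defaults to the
    condition's driving channel (head for whole-body and head-on-body
    rotations, body for body-under-head rotations).
    """
    y, X, segs, channel = _prepare(rate, stim, channel)
    grams = _segment_grams(y, X, segs)
    coeffs6, bias, rss = _fit_from_grams(grams)
    return _package(coeffs6, bias, rss, y, X, segs, channel, freq, modality)


def bootstrap_prune(
    rate: RateTrace | np.ndarray,
    stim: ConditionStimulus,
    channel: Channel | str | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng_seed: int | np.random.Generator | None = None,
    freq: float = 1.0,
    modality: Modality = Modality.VESTIBULAR,
) -> KinematicCoefficients:
    """Bootstrap coefficient significance and prune non-significant terms.

    Movement segments are resampled with replacement (jointly across both
    directions, respecting temporal autocorrelation) ``n_boot`` times and the
    model refit sign-unconstrained per draw (the constrained estimator folds
    at zero, which would make zero-coverage vanish). Per-coefficient
    (1 − alpha) confidence intervals are symmetrized bootstrap intervals,
    θ̂ ± q_{1−alpha/2}(|θ* − θ̂|), which hold their nominal coverage better
    than raw percentile intervals when only a few tens of segments are
    resampled. Any coefficient whose interval contains zero — including
    intervals touching the zero boundary — is set to zero and the constrained
    model is refit with the remaining terms. Deterministic under a fixed seed.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for stable percentile CIs",
                      stacklevel=2)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    y, X, segs, channel = _prepare(rate, stim, channel)
    if sum(len(s) for s in segs.values()) < 5:
        warnings.warn("fewer than 5 segments: bootstrap CIs will be unstable",
                      stacklevel=2)
    grams = _segment_grams(y, X, segs)
    all_idx = np.arange(len(grams))
    theta_hat = _solve_unconstrained(*_assemble(grams)[:2])
    boot_coeffs = np.empty((n_boot, 7))
    for bi in range(n_boot):
        picks = rng.choice(all_idx, size=len(all_idx), replace=True)
        G, h, _, _ = _assemble(grams, picks)
        boot_coeffs[bi] = _solve_unconstrained(G, h)
    half_width = np.percentile(
        np.abs(boot_coeffs - theta_hat), 100 * (1 - alpha / 2.0), axis=0
    )
    lo = theta_hat - half_width
    hi = theta_hat + half_width
    significant6 = ~((lo[:6] <= 0.0) & (hi[:6] >= 0.0))  # zero-spanning prunes

    coeffs6, bias, rss = _fit_from_grams(grams, active=significant6)
    ci = {}
    signif = {}
    for d in Direction:
        off = 0 if d is Direction.IPSI else 3
        ci[d] = {
            name: (float(lo[off + j]), float(hi[off + j]))
            for j, name in enumerate(_COEF_NAMES)
        }
        signif[d] = {
            name: bool(significant6[off + j]) for j, name in enumerate(_COEF_NAMES)
        }
    return _package(
        coeffs6, bias, rss, y, X, segs, channel, freq, modality, ci=ci, signif=signif
    )


def to_response_vector(
    coeffs: KinematicCoefficients | DirectionCoefficients,
    direction: Direction | str = Direction.IPSI,
    freq: float | None = None,
    modality: Modality | None = None,
) -> ResponseVector:
    """Convert a direction's coefficient triple into its (S, phase) phasor.

    Sensitivity is the gain relative to angular velocity; phase is
    quadrant-aware (atan2), so anti-phase responses of the non-positive branch
    land beyond ±90°. All-zero coefficients yield sensitivity 0 with the
    ``degenerate`` flag set (phase undefined).
    """
    direction = Direction(direction)
    if isinstance(coeffs, KinematicCoefficients):
        freq = coeffs.freq if freq is None else freq
        modality = coeffs.modality if modality is None else modality
        dirfit = coeffs.direction(direction)
    else:
        freq = 1.0 if freq is None else freq
        modality = Modality.VESTIBULAR if modality is None else modality
        dirfit = coeffs
    triple = np.asarray(dirfit.triple, dtype=float)
    if np.all(triple == 0.0):
        return ResponseVector(
            sensitivity=0.0, phase_deg=0.0, frequency=freq,
            direction=direction, modality=modality, sign=0, degenerate=True,
        )
    sens, phase = coeffs_to_sensitivity_phase(*triple, freq)
    sign = 1 if np.all(triple >= 0.0) else -1
    return ResponseVector(
        sensitivity=sens, phase_deg=phase, frequency=freq,
        direction=direction, modality=modality, sign=sign,
    )


def vaf(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Variance accounted for: 1 − var(observed − fitted)/var(observed).

    Returns NaN for a constant observed trace (undefined).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have equal lengths")
    denom = np.var(observed)
    if denom == 0.0:
        return float("nan")
    return float(1.0 - np.var(observed - fitted) / denom)
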