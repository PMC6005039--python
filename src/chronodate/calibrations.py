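"""Fossil calibration densities on node ages.

Five families are supported, written the way dating software prints them
(ages in units of 100 My):

``B(tL, tU, pL, pU)``
    Uniform between a minimum ``tL`` and maximum ``tU`` with *soft bounds*:
    the age escapes below ``tL`` with probability ``pL`` (power-law tail
    matched continuously at ``tL``) and above ``tU`` with probability ``pU``
    (exponential tail matched at ``tU``).
``L(tL, p, c, pL)``
    Truncated Cauchy above a minimum ``tL``: location ``tL*(1+p)``, scale
    ``c*tL``, carrying mass ``1-pL``; below ``tL`` a continuity-matched
    power tail carries ``pL`` (default 5%).
``ST(xi, omega, alpha, nu)``
    Skew-t (location, scale, shape, degrees of freedom).
``S2N(w, xi1, omega1, alpha1, xi2, omega2, alpha2)``
    Two-component skew-normal mixture with weight ``w`` on the first.
``G(a, b)``
    Gamma with shape ``a`` and rate ``b`` (mean ``a/b``).

``FIXED(t)`` pins a node age exactly (used e.g. for a fixed root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "CalibrationDensity",
    "SoftBoundUniform",
    "TruncatedCauchy",
    "SkewT",
    "SkewNormalMixture",
    "GammaDensity",
    "FixedAge",
    "parse_calibration",
    "format_calibration",
    "fit_skew_t_ml",
    "fit_gamma_moments",
    "SkewTFit",
]


class CalibrationDensity:
    """Base class: a proper density on (0, inf) for one node age."""

    tag: str = "?"

    @property
    def params(self) -> tuple[float, ...]:
        raise NotImplementedError

    def pdf(self, t):
        raise NotImplementedError

    def logpdf(self, t):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(t))

    def cdf(self, t):
        raise NotImplementedError

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0,1), got {q}")
        lo, hi = self._bracket()
        return float(optimize.brentq(lambda t: self.cdf(t) - q, lo, hi, xtol=1e-12))

    def sample(self, n: int, seed=None) -> np.ndarray:
        raise NotImplementedError

    def _bracket(self) -> tuple[float, float]:
        """Interval guaranteed to contain every nontrivial quantile."""
        raise NotImplementedError

    def __repr__(self) -> str:
        return format_calibration(self)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CalibrationDensity)
            and self.tag == other.tag
            and self.params == other.params
        )


@dataclass(eq=False, repr=False)
class SoftBoundUniform(CalibrationDensity):
    t_min: float
    t_max: float
    p_lower: float = 0.025
    p_upper: float = 0.025

    tag = "B"

    def __post_init__(self):
        if not (0 <= self.t_min < self.t_max):
            raise ValueError("need 0 <= t_min < t_max")
        if not (0 < self.p_upper and 0 <= self.p_lower and self.p_lower + self.p_upper < 1):
            raise ValueError("tail probabilities must be positive and sum below 1")
        if self.t_min == 0:
            self.p_lower = 0.0
        # density of the uniform core, and tail shapes matched to it
        self._h = (1 - self.p_lower - self.p_upper) / (self.t_max - self.t_min)
        self._theta_lower = (
            self._h * self.t_min / self.p_lower if self.p_lower > 0 else np.inf
        )
        self._theta_upper = self._h / self.p_upper

    @property
    def params(self):
        return (self.t_min, self.t_max, self.p_lower, self.p_upper)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        core = (t >= self.t_min) & (t <= self.t_max)
        out[core] = self._h
        if self.p_lower > 0:
            lo = (t > 0) & (t < self.t_min)
            # power tail in log space: theta can be large for tight bounds
            out[lo] = np.exp(
                math.log(self.p_lower * self._theta_lower / self.t_min)
                + (self._theta_lower - 1) * (np.log(t[lo]) - math.log(self.t_min))
            )
        hi = t > self.t_max
        out[hi] = (
            self.p_upper * self._theta_upper * np.exp(-self._theta_upper * (t[hi] - self.t_max))
        )
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.p_lower > 0:
            lo = (t > 0) & (t < self.t_min)
            out[lo] = self.p_lower * np.exp(
                self._theta_lower * (np.log(t[lo]) - math.log(self.t_min))
            )
        core = (t >= self.t_min) & (t <= self.t_max)
        out[core] = self.p_lower + self._h * (t[core] - self.t_min)
        hi = t > self.t_max
        out[hi] = 1 - self.p_upper * np.exp(-self._theta_upper * (t[hi] - self.t_max))
        return out if out.ndim else float(out)

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0,1), got {q}")
        if q < self.p_lower:
            return self.t_min * (q / self.p_lower) ** (1 / self._theta_lower)
        if q <= 1 - self.p_upper:
            return self.t_min + (q - self.p_lower) / self._h
        return self.t_max - math.log((1 - q) / self.p_upper) / self._theta_upper

    def sample(self, n, seed=None):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        return np.array([self.quantile(x) for x in u])

    def _bracket(self):
        return (1e-300, self.t_max + 60 / self._theta_upper)


@dataclass(eq=False, repr=False)
class TruncatedCauchy(CalibrationDensity):
    """Minimum-bound calibration with a heavy Cauchy tail above ``t_min``."""

    t_min: float
    p: float = 0.1
    c: float = 2.0
    p_lower: float = 0.05

    tag = "L"

    def __post_init__(self):
        if self.t_min <= 0 or self.p <= 0 or self.c <= 0:
            raise ValueError("t_min, p, c must be positive")
        if not 0 < self.p_lower < 1:
            raise ValueError("p_lower must be in (0,1)")
        self._loc = self.t_min * (1 + self.p)
        self._scale = self.c * self.t_min
        self._cau = stats.cauchy(loc=self._loc, scale=self._scale)
        self._tail = 1 - self._cau.cdf(self.t_min)  # Cauchy mass above t_min
        f_at_min = (1 - self.p_lower) * self._cau.pdf(self.t_min) / self._tail
        self._theta = self.t_min * f_at_min / self.p_lower

    @property
    def params(self):
        return (self.t_min, self.p, self.c, self.p_lower)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        hi = t >= self.t_min
        out[hi] = (1 - self.p_lower) * self._cau.pdf(t[hi]) / self._tail
        lo = (t > 0) & (t < self.t_min)
        out[lo] = np.exp(
            math.log(self.p_lower * self._theta / self.t_min)
            + (self._theta - 1) * (np.log(t[lo]) - math.log(self.t_min))
        )
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        lo = (t > 0) & (t < self.t_min)
        out[lo] = self.p_lower * np.exp(
            self._theta * (np.log(t[lo]) - math.log(self.t_min))
        )
        hi = t >= self.t_min
        out[hi] = self.p_lower + (1 - self.p_lower) * (
            self._cau.cdf(t[hi]) - self._cau.cdf(self.t_min)
        ) / self._tail
        return out if out.ndim else float(out)

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0,1), got {q}")
        if q < self.p_lower:
            return self.t_min * (q / self.p_lower) ** (1 / self._theta)
        u = self._cau.cdf(self.t_min) + (q - self.p_lower) / (1 - self.p_lower) * self._tail
        return float(self._cau.ppf(u))

    def sample(self, n, seed=None):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        return np.array([self.quantile(x) for x in u])

    def _bracket(self):
        return (1e-300, float(self._cau.ppf(1 - 1e-13)))


def _skew_t_logpdf(x, xi, omega, alpha, nu):
    z = (np.asarray(x, dtype=float) - xi) / omega
    base = stats.t.logpdf(z, df=nu)
    arg = alpha * z * np.sqrt((nu + 1) / (z * z + nu))
    skew = stats.t.logcdf(arg, df=nu + 1)
    return math.log(2.0) - math.log(omega) + base + skew


@dataclass(eq=False, repr=False)
class SkewT(CalibrationDensity):
    xi: float
    omega: float
    alpha: float
    nu: float

    tag = "ST"

    def __post_init__(self):
        if self.omega <= 0 or self.nu <= 0:
            raise ValueError("omega and nu must be positive")

    @property
    def params(self):
        return (self.xi, self.omega, self.alpha, self.nu)

    def logpdf(self, t):
        return _skew_t_logpdf(t, self.xi, self.omega, self.alpha, self.nu)

    def pdf(self, t):
        return np.exp(self.logpdf(t))

    def _cdf_interp(self):
        # dense monotone interpolant of the cdf; abscissae follow Student-t
        # quantiles so both tails are resolved
        if not hasattr(self, "_cdf_cache"):
            qs = np.linspace(1e-10, 1 - 1e-10, 6001)
            zs = stats.t.ppf(qs, df=min(self.nu, 1e6))
            xs = np.unique(self.xi + self.omega * np.concatenate([zs, -zs]))
            ps = self.pdf(xs)
            fs = integrate.cumulative_trapezoid(ps, xs, initial=0.0)
            fs = np.clip(fs, 0.0, 1.0)
            from scipy.interpolate import PchipInterpolator

            self._cdf_cache = (xs, PchipInterpolator(xs, fs, extrapolate=False))
        return self._cdf_cache

    def cdf(self, t):
        xs, interp = self._cdf_interp()
        scalar = np.isscalar(t)
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.where(ts <= xs[0], 0.0, np.where(ts >= xs[-1], 1.0, interp(np.clip(ts, xs[0], xs[-1]))))
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def sample(self, n, seed=None):
        rng = np.random.default_rng(seed)
        delta = self.alpha / math.sqrt(1 + self.alpha**2)
        u0 = np.abs(rng.standard_normal(n))
        u1 = rng.standard_normal(n)
        z = delta * u0 + math.sqrt(1 - delta**2) * u1  # standard skew-normal
        w = rng.chisquare(self.nu, size=n) / self.nu
        return self.xi + self.omega * z / np.sqrt(w)

    def _bracket(self):
        xs, _ = self._cdf_interp()
        return (float(xs[0]), float(xs[-1]))


@dataclass(eq=False, repr=False)
class SkewNormalMixture(CalibrationDensity):
    w: float
    xi1: float
    omega1: float
    alpha1: float
    xi2: float
    omega2: float
    alpha2: float

    tag = "S2N"

    def __post_init__(self):
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must be in (0,1)")
        if self.omega1 <= 0 or self.omega2 <= 0:
            raise ValueError("scales must be positive")
        self._c1 = stats.skewnorm(self.alpha1, loc=self.xi1, scale=self.omega1)
        self._c2 = stats.skewnorm(self.alpha2, loc=self.xi2, scale=self.omega2)

    @property
    def params(self):
        return (self.w, self.xi1, self.omega1, self.alpha1, self.xi2, self.omega2, self.alpha2)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = self.w * self._c1.pdf(t) + (1 - self.w) * self._c2.pdf(t)
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = self.w * self._c1.cdf(t) + (1 - self.w) * self._c2.cdf(t)
        return out if out.ndim else float(out)

    def sample(self, n, seed=None):
        rng = np.random.default_rng(seed)
        pick = rng.uniform(size=n) < self.w
        out = np.empty(n)
        out[pick] = self._c1.rvs(size=int(pick.sum()), random_state=rng)
        out[~pick] = self._c2.rvs(size=int((~pick).sum()), random_state=rng)
        return out

    def _bracket(self):
        lo = min(self.xi1 - 40 * self.omega1, self.xi2 - 40 * self.omega2)
        hi = max(self.xi1 + 40 * self.omega1, self.xi2 + 40 * self.omega2)
        return (lo, hi)


@dataclass(eq=False, repr=False)
class GammaDensity(CalibrationDensity):
    a: float
    b: float  # rate

    tag = "G"

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("shape and rate must be positive")
        self._g = stats.gamma(self.a, scale=1.0 / self.b)

    @property
    def params(self):
        return (self.a, self.b)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = self._g.pdf(t)
        return out if np.ndim(out) else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = self._g.cdf(t)
        return out if np.ndim(out) else float(out)

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0,1), got {q}")
        return float(self._g.ppf(q))

    def sample(self, n, seed=None):
        rng = np.random.default_rng(seed)
        return self._g.rvs(size=n, random_state=rng)

    def _bracket(self):
        return (1e-300, float(self._g.ppf(1 - 1e-14)))


@dataclass(eq=False, repr=False)
class FixedAge(CalibrationDensity):
    """Point mass: the node age is fixed, not sampled."""

    age: float

    tag = "FIXED"

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("fixed age must be positive")

    @property
    def params(self):
        return (self.age,)

    def pdf(self, t):
        raise TypeError("a fixed age has no density; the node is not sampled")

    cdf = pdf

    def sample(self, n, seed=None):
        return np.full(n, self.age)


_FAMILIES = {
    "B": (SoftBoundUniform, (2, 4)),
    "L": (TruncatedCauchy, (1, 4)),
    "ST": (SkewT, (4, 4)),
    "S2N": (SkewNormalMixture, (7, 7)),
    "G": (GammaDensity, (2, 2)),
    "FIXED": (FixedAge, (1, 1)),
}


def parse_calibration(text: str) -> CalibrationDensity:
    """Parse a calibration annotation such as ``B(0.25,0.337,0.01,0.1)``."""
    from .treeio import CalibrationError  # local import to avoid a cycle

    text = text.strip().strip("'\"")
    if "(" not in text or not text.endswith(")"):
        raise CalibrationError(f"malformed calibration annotation {text!r}")
    tag, argstr = text.split("(", 1)
    tag = tag.strip().upper()
    if tag not in _FAMILIES:
        raise CalibrationError(f"unknown calibration family {tag!r}")
    cls, (nmin, nmax) = _FAMILIES[tag]
    try:
        args = [float(x) for x in argstr[:-1].split(",") if x.strip() != ""]
    except ValueError as err:
        raise CalibrationError(f"non-numeric calibration parameter in {text!r}") from err
    if not (nmin <= len(args) <= nmax):
        raise CalibrationError(
            f"family {tag} takes {nmin}..{nmax} parameters, got {len(args)}"
        )
    try:
        return cls(*args)
    except ValueError as err:
        raise CalibrationError(f"invalid parameters for {tag}: {err}") from err


def format_calibration(d: CalibrationDensity, digits: int = 6) -> str:
    args = ",".join(f"{p:.{digits}g}" for p in d.params)
    return f"{d.tag}({args})"


# -- fitting ----------------------------------------------------------------


@dataclass
class SkewTFit:
    density: SkewT
    loglik: float
    converged: bool


def _skew_t_negloglik(theta, x):
    xi, logw, alpha, lognu = theta
    omega = math.exp(logw)
    nu = math.exp(lognu)
    ll = _skew_t_logpdf(x, xi, omega, alpha, nu)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def fit_skew_t_ml(samples, seed: int = 0) -> SkewTFit:
    """Maximum-likelihood skew-t fit to a posterior age sample.

    Shape and degrees of freedom are weakly identified, so the optimizer is
    restarted from a moment-based start plus four jittered starts; the best
    local optimum is returned with a convergence flag (never an exception).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.std(x) == 0:
        fallback = SkewT(float(np.mean(x)), max(float(np.std(x)), 1e-8), 0.0, 100.0)
        return SkewTFit(fallback, -np.inf, False)
    m, s = float(np.mean(x)), float(np.std(x))
    skew = float(stats.skew(x))
    alpha0 = float(np.clip(5 * skew, -20, 20))
    base = np.array([m, math.log(s), alpha0, math.log(20.0)])
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(4):
        jitter = rng.normal(scale=[0.3 * s, 0.4, 2.0, 0.8])
        starts.append(base + jitter)
    bounds = [(None, None), (None, None), (-300, 300), (math.log(2.1), math.log(1e4))]
    best = None
    for s0 in starts:
        s0 = np.clip(s0, [-np.inf, -np.inf, -300, math.log(2.1)], [np.inf, np.inf, 300, math.log(1e4)])
        try:
            res = optimize.minimize(
                _skew_t_negloglik, s0, args=(x,), method="L-BFGS-B", bounds=bounds
            )
        except Exception:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        fallback = SkewT(m, s, 0.0, 100.0)
        return SkewTFit(fallback, -np.inf, False)
    xi, logw, alpha, lognu = best.x
    density = SkewT(float(xi), math.exp(logw), float(alpha), math.exp(lognu))
    return SkewTFit(density, -float(best.fun), bool(best.success) and x.size >= 100)


def fit_gamma_moments(samples) -> GammaDensity:
    """Moment-matched gamma: shape = mean^2/var, rate = mean/var."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(x <= 0):
        raise ValueError("samples must be positive")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var == 0:
        raise ValueError("zero variance: gamma moments undefined")
    return GammaDensity(mean * mean / var, mean / var)
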