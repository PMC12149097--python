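"""Parametric survival families used for extrapolation.

Five candidate families are supported: exponential, Weibull, log-normal,
log-logistic and Gompertz.  Each family exposes the survival function,
log-density and log-survival on its *natural* parameter scale, plus the
transform between the natural scale and the unconstrained optimisation
scale (log for positive parameters, identity otherwise) and moment-based
starting values for maximum likelihood.

Parameterisations (t > 0):

- exponential(rate):        S(t) = exp(-rate * t)
- weibull(shape, scale):    S(t) = exp(-(t/scale)**shape)
- lognormal(mu, sigma):     S(t) = 1 - Phi((log t - mu) / sigma)
- loglogistic(shape, scale):S(t) = 1 / (1 + (t/scale)**shape)
- gompertz(a, b):           h(t) = a * exp(b t);  S(t) = exp(-a/b (e^{bt}-1))
  with a > 0 and b unrestricted (b < 0 gives a decreasing hazard and a
  defective distribution, the usual health-economics convention); b -> 0
  recovers the exponential.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np
from scipy import stats

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

_B_TINY = 1e-9  # |b| below this: treat Gompertz as exponential limit


class Family(NamedTuple):
    name: str
    n_params: int
    param_names: tuple[str, ...]
    logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    logsf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    sf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    to_unconstrained: Callable[[np.ndarray], np.ndarray]
    from_unconstrained: Callable[[np.ndarray], np.ndarray]
    starts: Callable[[np.ndarray, np.ndarray], list[np.ndarray]]


def _exp_logpdf(t, p):
    return np.log(p[0]) - p[0] * t


def _exp_logsf(t, p):
    return -p[0] * t


def _wei_logpdf(t, p):
    k, lam = p
    z = t / lam
    return np.log(k / lam) + (k - 1) * np.log(z) - z**k


def _wei_logsf(t, p):
    k, lam = p
    return -((t / lam) ** k)


def _lnorm_logpdf(t, p):
    mu, sig = p
    return stats.norm.logpdf(np.log(t), mu, sig) - np.log(t)


def _lnorm_logsf(t, p):
    mu, sig = p
    return stats.norm.logsf(np.log(t), mu, sig)


def _llog_logpdf(t, p):
    b, a = p  # shape, scale
    z = np.log(t / a) * b
    # f(t) = (b/a) z'^(b-1) / (1+z')^2 with z' = (t/a)^b; stable via log1p
    return np.log(b / a) + (b - 1) * np.log(t / a) - 2 * np.logaddexp(0.0, z)


def _llog_logsf(t, p):
    b, a = p
    return -np.logaddexp(0.0, b * np.log(t / a))


def _gomp_logpdf(t, p):
    a, b = p
    if abs(b) < _B_TINY:
        return np.log(a) - a * t
    return np.log(a) + b * t - a / b * np.expm1(b * t)


def _gomp_logsf(t, p):
    a, b = p
    if abs(b) < _B_TINY:
        return -a * t
    return -a / b * np.expm1(b * t)


def _log_all(p):
    return np.log(p)


def _exp_all(x):
    return np.exp(x)


def _gomp_to_unc(p):
    return np.array([np.log(p[0]), p[1]])


def _gomp_from_unc(x):
    return np.array([np.exp(x[0]), x[1]])


def _km_moments(time, event):
    """Crude location/spread of log-time among events (fallback: all times)."""
    t = time[event == 1]
    if t.size < 2:
        t = time
    logs = np.log(np.maximum(t, 1e-12))
    return float(np.mean(logs)), float(max(np.std(logs), 0.1))


def _exp_starts(time, event):
    rate = max(event.sum(), 1.0) / time.sum()
    return [np.array([rate])]


def _wei_starts(time, event):
    m, s = _km_moments(time, event)
    # log-time SD of a Weibull is ~1.283/shape; mean log-time ~ log(scale)-0.5772/shape
    k = 1.283 / s
    return [
        np.array([k, np.exp(m + 0.5772 / k)]),
        np.array([1.0, np.exp(m)]),
        np.array([0.5 * k, np.exp(m)]),
    ]


def _lnorm_starts(time, event):
    m, s = _km_moments(time, event)
    return [np.array([m, s]), np.array([m, 2 * s]), np.array([m + s, s])]


def _llog_starts(time, event):
    m, s = _km_moments(time, event)
    # log-logistic log-time SD = pi/(sqrt(3)*shape)
    b = np.pi / (np.sqrt(3.0) * s)
    return [np.array([b, np.exp(m)]), np.array([1.0, np.exp(m)]), np.array([2 * b, np.exp(m)])]


def _gomp_starts(time, event):
    rate = max(event.sum(), 1.0) / time.sum()
    return [
        np.array([rate, 0.01]),
        np.array([rate, -0.01]),
        np.array([0.5 * rate, 0.05]),
    ]


_REGISTRY: dict[str, Family] = {
    "exponential": Family(
        "exponential", 1, ("rate",),
        _exp_logpdf, _exp_logsf, lambda t, p: np.exp(_exp_logsf(t, p)),
        _log_all, _exp_all, _exp_starts,
    ),
    "weibull": Family(
        "weibull", 2, ("shape", "scale"),
        _wei_logpdf, _wei_logsf, lambda t, p: np.exp(_wei_logsf(t, p)),
        _log_all, _exp_all, _wei_starts,
    ),
    "lognormal": Family(
        "lognormal", 2, ("mu", "sigma"),
        _lnorm_logpdf, _lnorm_logsf,
        lambda t, p: stats.norm.sf(np.log(np.maximum(t, 1e-300)), p[0], p[1]),
        lambda p: np.array([p[0], np.log(p[1])]),
        lambda x: np.array([x[0], np.exp(x[1])]),
        _lnorm_starts,
    ),
    "loglogistic": Family(
        "loglogistic", 2, ("shape", "scale"),
        _llog_logpdf, _llog_logsf, lambda t, p: np.exp(_llog_logsf(t, p)),
        _log_all, _exp_all, _llog_starts,
    ),
    "gompertz": Family(
        "gompertz", 2, ("rate", "shape"),
        _gomp_logpdf, _gomp_logsf, lambda t, p: np.exp(_gomp_logsf(t, p)),
        _gomp_to_unc, _gomp_from_unc, _gomp_starts,
    ),
}


def get_family(name: str) -> Family:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown survival family {name!r}; expected one of {FAMILIES}"
        ) from None


def sample(name: str, params, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event times from a family (inverse-CDF where needed)."""
    p = np.asarray(params, dtype=float)
    if name == "exponential":
        return rng.exponential(1.0 / p[0], size)
    if name == "weibull":
        return p[1] * rng.weibull(p[0], size)
    if name == "lognormal":
        return rng.lognormal(p[0], p[1], size)
    if name == "loglogistic":
        u = rng.uniform(size=size)
        return p[1] * (u / (1 - u)) ** (1.0 / p[0])
    if name == "gompertz":
        a, b = p
        u = rng.uniform(size=size)
        if abs(b) < _B_TINY:
            return -np.log(u) / a
        # S(t) = u  =>  t = log(1 - (b/a) log u)/b ; with b<0 the distribution
        # is defective: draws with no solution live at +inf.
        arg = 1.0 - (b / a) * np.log(u)
        t = np.full(size, np.inf)
        ok = arg > 0
        t[ok] = np.log(arg[ok]) / b
        return t
    raise ValueError(f"unknown survival family {name!r}")
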