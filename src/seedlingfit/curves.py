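"""Closed-form growth and decay curves for early seedling trajectories.

Three mean functions cover the trajectories measured on young bean
seedlings:

* **expolinear** — an exponential juvenile phase that transitions smoothly
  into linear growth of slope ``Cm`` (maximum absolute growth rate) with
  x-intercept ``tb``; used for total root length and branch counts.
* **Gompertz** — an asymmetric sigmoid with asymptote ``Wf``, maximum
  relative growth rate ``k`` attained at time ``TT`` (where the curve passes
  through ``Wf/e``); used for primary/basal root length, leaf area and
  seedling dry weight.
* **decay** — a logistic-type decline from an initial plateau ``Max`` to a
  final plateau ``Min`` with mid-point at ``TT``; used for the
  remobilisation of cotyledon dry weight.  The steepness ``rate`` is fixed
  at 1 per day by default, matching the three-parameter form whose degrees
  of freedom the grouped fits assume; it can be freed explicitly.

All evaluations are elementwise over a time array, numerically stable for
exponent arguments up to +/-700, and paired with analytic parameter
gradients (needed by the generalized least-squares fitter for asymptotic
standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "ExpolinearParams",
    "GompertzParams",
    "DecayParams",
    "expolinear_value",
    "gompertz_value",
    "decay_value",
    "gradient",
    "FAMILIES",
    "family_info",
]

_MAX_EXP = 700.0  # exp() stays finite below this for float64


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    return t


@dataclass(frozen=True)
class ExpolinearParams:
    """Expolinear parameters: linear-phase slope, relative rate, intercept.

    cm : maximum absolute growth rate (response units per day), > 0
    rm : maximum relative growth rate (per day), > 0
    tb : x-intercept of the linear phase (days)
    """

    cm: float
    rm: float
    tb: float

    def __post_init__(self):
        if not (self.cm > 0 and self.rm > 0):
            raise ValueError("expolinear requires cm > 0 and rm > 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.cm, self.rm, self.tb], dtype=float)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters: asymptote, relative rate, inflection time.

    wf : asymptotic maximum (response units), > 0
    k  : maximum relative growth rate (per day), > 0
    tt : time of maximum relative growth rate (days); Y(tt) = wf / e
    """

    wf: float
    k: float
    tt: float

    def __post_init__(self):
        if not (self.wf > 0 and self.k > 0):
            raise ValueError("Gompertz requires wf > 0 and k > 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.wf, self.k, self.tt], dtype=float)


@dataclass(frozen=True)
class DecayParams:
    """Logistic decay parameters: plateaus, mid-point time, steepness.

    maximum : initial plateau (g), > minimum
    minimum : final plateau (g), >= 0
    tt      : time at which the curve reaches (maximum + minimum) / 2 (days)
    rate    : decay steepness (per day); fixed at 1 in the canonical
              three-parameter form
    """

    maximum: float
    minimum: float
    tt: float
    rate: float = 1.0

    def __post_init__(self):
        if not (self.maximum > self.minimum >= 0):
            raise ValueError("decay requires maximum > minimum >= 0")
        if not self.rate > 0:
            raise ValueError("decay requires rate > 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.maximum, self.minimum, self.tt, self.rate],
                        dtype=float)


# ---------------------------------------------------------------------------
# raw (array-parameter) evaluations, used by the fitter

def _expolinear(t, cm, rm, tb):
    # log-sum-exp form: (cm/rm) * ln(1 + exp(rm (t - tb))) never overflows
    return (cm / rm) * np.logaddexp(0.0, rm * (t - tb))


def _expolinear_grad(t, cm, rm, tb):
    u = rm * (t - tb)
    ell = np.logaddexp(0.0, u)
    s = expit(u)
    d_cm = ell / rm
    d_rm = (cm / rm) * ((t - tb) * s - ell / rm)
    d_tb = -cm * s
    return np.stack([d_cm, d_rm, d_tb], axis=-1)


def _gompertz(t, wf, k, tt):
    inner = np.exp(np.minimum(-k * (t - tt), _MAX_EXP))
    return wf * np.exp(-inner)


def _gompertz_grad(t, wf, k, tt):
    inner = np.exp(np.minimum(-k * (t - tt), _MAX_EXP))
    y = wf * np.exp(-inner)
    d_wf = y / wf
    d_k = y * inner * (t - tt)
    d_tt = -y * inner * k
    return np.stack([d_wf, d_k, d_tt], axis=-1)


def _decay(t, maximum, minimum, tt, rate=1.0):
    p = expit(-rate * (t - tt))
    return minimum + (maximum - minimum) * p


def _decay_grad(t, maximum, minimum, tt, rate=1.0):
    p = expit(-rate * (t - tt))
    pq = p * (1.0 - p)
    span = maximum - minimum
    d_max = p
    d_min = 1.0 - p
    d_tt = span * rate * pq
    d_rate = -span * (t - tt) * pq
    return np.stack([d_max, d_min, d_tt, d_rate], axis=-1)


@dataclass(frozen=True)
class _Family:
    name: str
    param_class: type
    param_names: tuple
    value: callable
    grad: callable
    increasing: bool


FAMILIES: Mapping[str, _Family] = {
    "expolinear": _Family("expolinear", ExpolinearParams, ("cm", "rm", "tb"),
                          _expolinear, _expolinear_grad, True),
    "gompertz": _Family("gompertz", GompertzParams, ("wf", "k", "tt"),
                        _gompertz, _gompertz_grad, True),
    "decay": _Family("decay", DecayParams, ("maximum", "minimum", "tt", "rate"),
                     _decay, _decay_grad, False),
}


def family_info(family: str) -> _Family:
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown curve family {family!r}; "
                         f"expected one of {sorted(FAMILIES)}") from None


# ---------------------------------------------------------------------------
# public, dataclass-parameter API

def expolinear_value(p: ExpolinearParams, t):
    """Expolinear curve Y(t) = (Cm/Rm) ln(1 + exp(Rm (t - tb)))."""
    return _expolinear(_check_time(t), p.cm, p.rm, p.tb)


def gompertz_value(p: GompertzParams, t):
    """Gompertz curve Y(t) = Wf exp(-exp(-k (t - TT)))."""
    return _gompertz(_check_time(t), p.wf, p.k, p.tt)


def decay_value(p: DecayParams, t):
    """Logistic decay Y(t) = Min + (Max - Min) / (1 + exp(rate (t - TT)))."""
    return _decay(_check_time(t), p.maximum, p.minimum, p.tt, p.rate)


def curve_value(family: str, p, t):
    """Evaluate any registered family from its parameter dataclass."""
    fam = family_info(family)
    return fam.value(_check_time(t), *p.to_array())


def gradient(family: str, p, t) -> np.ndarray:
    """Partial derivatives of the curve with respect to its parameters.

    Returns an array of shape ``t.shape + (n_params,)`` with columns in the
    declared parameter order of the family (decay includes the rate column).
    """
    fam = family_info(family)
    return fam.grad(_check_time(t), *p.to_array())


def params_from_mapping(family: str, values: Mapping[str, float]):
    """Build the parameter dataclass of a family from a name->value mapping."""
    fam = family_info(family)
    kwargs = {f.name: values[f.name] for f in fields(fam.param_class)
              if f.name in values}
    return fam.param_class(**kwargs)
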