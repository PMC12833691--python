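"""Mean-log-deviation inequality and ex-ante opportunity-inequality statistics.

The ex-ante parametric approach measures opportunity inequality as the
inequality of a counterfactual "smoothed" outcome distribution: each person is
assigned the outcome predicted from their circumstances (environment) alone,
so within-circumstance (effort) variation is averaged out.  With the mean log
deviation ``I`` as the index,

    theta_a = I(H_hat)            (absolute opportunity inequality)
    theta_r = I(H_hat) / I(H)     (relative opportunity inequality)

where ``H_hat`` are the fitted values of an environment-only model of health
``H``.  MLD is scale-invariant but translation-sensitive, so the positivity
shift applied to the transformed health variable is carried in the result and
must be shared by numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["mld", "IOpResult", "opportunity_inequality"]


def mld(values) -> float:
    """Mean log deviation ``(1/n) * sum(log(mean(y) / y_i))``.

    Zero iff all values are equal; invariant to rescaling by a positive
    constant; *not* invariant to translation.

    Parameters
    ----------
    values : array-like of positive floats

    Raises
    ------
    ValueError
        If any value is non-positive (apply a positivity shift first) or the
        input is empty.
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("mld: empty input")
    if not np.all(np.isfinite(y)):
        raise ValueError("mld: non-finite values")
    if np.any(y <= 0.0):
        raise ValueError(
            "mld requires strictly positive values; apply a positivity shift "
            f"(min value was {y.min():g})"
        )
    mu = y.mean()
    return float(np.log(mu) - np.mean(np.log(y)))


@dataclass
class IOpResult:
    """Opportunity-inequality statistics for one model and health variant."""

    total_mld: float
    absolute_iop: float
    relative_iop: float
    family: str = ""
    variant: str = ""
    shift: float = float("nan")
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "family": self.family,
            "variant": self.variant,
            "absolute_iop": self.absolute_iop,
            "relative_iop": self.relative_iop,
            "total_mld": self.total_mld,
            "shift": self.shift,
            **self.extra,
        }


def opportunity_inequality(fitted, actual, *, family: str = "", variant: str = "",
                           shift: float = float("nan")) -> IOpResult:
    """Compute theta_a and theta_r from fitted (smoothed) and actual health.

    ``fitted`` and ``actual`` must live on the same shifted positive scale.
    theta_r outside [0, 1] (possible for overfit smoothers in finite samples)
    triggers a warning but is never clipped.
    """
    fitted = np.asarray(fitted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if fitted.shape != actual.shape:
        raise ValueError("fitted and actual must have the same length")
    total = mld(actual)
    theta_a = mld(fitted)
    if total == 0.0:
        raise ValueError("total MLD is zero: relative opportunity inequality undefined")
    theta_r = theta_a / total
    if not 0.0 <= theta_r <= 1.0:
        warnings.warn(
            f"relative opportunity inequality {theta_r:.4f} outside [0, 1]; "
            "this can happen with overfit smoothers and is reported unclipped",
            stacklevel=2,
        )
    return IOpResult(total_mld=total, absolute_iop=theta_a, relative_iop=theta_r,
                     family=family, variant=variant, shift=shift)
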