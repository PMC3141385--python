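"""Treatment persistence and residual drug protection.

Two fitted curves drive the real-world alternative:

* the persistence curve ``P(T) = 1 - b·ln(T)`` (T in months, b = 0.196 for
  weekly oral bisphosphonates), clamped to 1 for T ≤ 1 month and floored at
  20% from 60 months to the end of the simulation; and
* the residual-protection (offset) curve ``y(T) = a·exp(k·T)`` (a = 13.5
  months, k = 0.048 /month) giving the total number of months of fracture
  protection earned by T months of treatment, with y(0) = 0.

Their combination gives the proportion of initiators still protected at any
month m since initiation: a woman treated for T months is protected up to
month y(T), and since y is increasing the protected proportion equals the
persistence survival evaluated at the shortest treatment duration whose
residual effect still covers month m.  The same construction, inverted, gives
the per-patient discontinuation-time sampler used by the microsimulation; the
closed form is retained as its deterministic oracle.

An ``uplift`` λ ∈ [0, 1] linearly mixes the real-world curve toward ideal
persistence, ``P_λ(T) = P(T) + λ·(1 - P(T))``, which the persistence-sweep
analysis uses (λ = 0 real world, λ = 1 ideal).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .params import PersistenceParams, ResidualEffectParams

_DEFAULT_PERSISTENCE = PersistenceParams(
    b=0.196, floor=0.20, floor_onset_months=60.0, min_duration_months=1.0
)
_DEFAULT_RESIDUAL = ResidualEffectParams(scale_months=13.5, rate_per_month=0.048)


def _check_uplift(uplift: float) -> None:
    if not 0.0 <= uplift <= 1.0:
        raise ValueError(f"uplift must be in [0, 1], got {uplift}")


def persistence_at(
    T: float,
    params: PersistenceParams | None = None,
    uplift: float = 0.0,
) -> float:
    """Proportion of initiators still on treatment after T months.

    Returns 1 for T ≤ the minimum evaluable duration (1 month), the fitted
    logarithmic curve below the floor onset, and the floor (0.20) thereafter;
    always clamped to [floor, 1].
    """
    p = params or _DEFAULT_PERSISTENCE
    _check_uplift(uplift)
    if T < 0:
        raise ValueError(f"treatment duration must be >= 0, got {T}")
    if T <= p.min_duration_months:
        base = 1.0
    else:
        base = 1.0 - p.b * math.log(T)
    base = min(1.0, max(p.floor, base))
    if T >= p.floor_onset_months:
        base = p.floor
    return base + uplift * (1.0 - base)


def protection_duration(T, params: ResidualEffectParams | None = None):
    """Total months of protection y(T) earned by T months of treatment.

    y(0) = 0 (never-initiated protection is nil; the exponential alone would
    give y(0) = a) and y(T) = a·exp(k·T) otherwise.  Accepts scalars or
    arrays; np.inf maps to np.inf (never-discontinuers are protected for the
    whole horizon).
    """
    r = params or _DEFAULT_RESIDUAL
    arr = np.asarray(T, dtype=float)
    if np.any(arr < 0):
        raise ValueError("treatment duration must be >= 0")
    y = np.where(arr > 0, r.scale_months * np.exp(r.rate_per_month * arr), 0.0)
    return float(y) if np.isscalar(T) or arr.ndim == 0 else y


def required_treatment_months(m: float, params: ResidualEffectParams | None = None) -> float:
    """Shortest treatment duration T* whose residual protection covers month m.

    Inverse of y: T*(m) = ln(m/a)/k, floored at 0 for m ≤ a (any initiator is
    protected through month a = 13.5).
    """
    r = params or _DEFAULT_RESIDUAL
    if m < 0:
        raise ValueError("month must be >= 0")
    if m <= r.scale_months:
        return 0.0
    return math.log(m / r.scale_months) / r.rate_per_month


def protected_proportion(
    m: float,
    persistence: PersistenceParams | None = None,
    residual: ResidualEffectParams | None = None,
    uplift: float = 0.0,
) -> float:
    """Proportion of the initiating cohort protected at month m.

    Equals ``persistence_at(min(m, T*(m)))``: whoever is still treated at
    month m is protected, and whoever stopped at T ≥ T*(m) is still covered by
    the residual effect.  Deterministic oracle for the per-patient sampler.
    """
    if m < 0:
        raise ValueError("month must be >= 0")
    if m == 0:
        return 1.0
    t_star = required_treatment_months(m, residual)
    return persistence_at(min(m, t_star), persistence, uplift=uplift)


def sample_discontinuation(
    u: float,
    params: PersistenceParams | None = None,
    uplift: float = 0.0,
) -> float:
    """Invert one uniform(0,1) draw into a discontinuation time in months.

    Draws below the (uplifted) floor mass never discontinue within the
    horizon (returns ``inf``); otherwise T = exp(((1-u)/(1-λ))/b), clamped to
    at least the minimum evaluable duration.  The survival function of the
    result is exactly ``persistence_at``.
    """
    p = params or _DEFAULT_PERSISTENCE
    _check_uplift(uplift)
    if not 0.0 < u < 1.0:
        raise ValueError(f"u must be in (0, 1), got {u}")
    floor_u = p.floor + uplift * (1.0 - p.floor)
    if u < floor_u:
        return math.inf
    T = math.exp(((1.0 - u) / (1.0 - uplift)) / p.b)
    return max(T, p.min_duration_months)


def sample_discontinuation_times(
    u: np.ndarray,
    params: PersistenceParams | None = None,
    uplift: float = 0.0,
) -> np.ndarray:
    """Vectorized :func:`sample_discontinuation` for the engine."""
    p = params or _DEFAULT_PERSISTENCE
    _check_uplift(uplift)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("all u must be in (0, 1)")
    floor_u = p.floor + uplift * (1.0 - p.floor)
    T = np.full(u.shape, np.inf)
    if uplift < 1.0:
        mask = u >= floor_u
        T[mask] = np.maximum(
            np.exp(((1.0 - u[mask]) / (1.0 - uplift)) / p.b), p.min_duration_months
        )
    return T


def cycle_drug_exposure(
    cycle: int,
    params: PersistenceParams | None = None,
    uplift: float = 0.0,
    horizon_cycles: int = 10,
    out_of_horizon: str = "error",
) -> float:
    """Cohort-mean fraction of cycle ``cycle`` (1-based year) spent on drug.

    The cohort form: the mean of ``persistence_at`` over the 12 months of the
    cycle (end-of-month convention, months 12·(c-1)+1 .. 12·c).  The
    individual form used by the engine is months-on-drug/12 from the sampled
    discontinuation time; both agree in expectation.
    """
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    if cycle > horizon_cycles:
        if out_of_horizon == "zero":
            return 0.0
        raise ValueError(f"cycle {cycle} beyond horizon of {horizon_cycles}")
    months = 12 * (cycle - 1) + np.arange(1, 13)
    return float(np.mean([persistence_at(m, params, uplift=uplift) for m in months]))


def protection_schedule(
    persistence: PersistenceParams | None = None,
    residual: ResidualEffectParams | None = None,
    horizon_months: int = 120,
    uplift: float = 0.0,
) -> pd.DataFrame:
    """Month-by-month protected proportion and per-cycle drug exposure.

    Columns: month, protected_proportion, and (on month rows that close a
    cycle) the cycle's mean drug exposure; exportable to CSV as the model's
    part-A→part-B transfer schedule.
    """
    months = np.arange(0, horizon_months + 1)
    prot = [protected_proportion(m, persistence, residual, uplift=uplift) for m in months]
    df = pd.DataFrame({"month": months, "protected_proportion": prot})
    df["cycle"] = np.maximum(1, (df["month"] + 11) // 12)
    exposures = {
        c: cycle_drug_exposure(c, persistence, uplift=uplift,
                               horizon_cycles=max(1, horizon_months // 12))
        for c in range(1, max(1, horizon_months // 12) + 1)
    }
    df["cycle_drug_exposure"] = df["cycle"].map(exposures)
    return df
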