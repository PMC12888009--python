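"""Dose–response bioassays: probit LD50/ED50, potency and dosing algebra.

Lethality and neutralization assays are quantal: groups of mice receive a
dose (μg venom, or mg venom per g antivenom against a fixed 5xLD50 venom
challenge) and deaths are counted at 48 h.  The median dose is estimated by
maximum-likelihood binomial regression with a probit link on log10(dose)
(Finney's probit analysis), with delta-method 95% confidence limits on the
log-median.

Downstream algebra: for a challenge of n LD50s the neutralization potency
is P = ED50·(n-1)/n (one LD50 remains unneutralized at the 50% endpoint);
P over the antivenom's maximal binding capacity gives the percentage of
toxin-binding antibodies that contribute to neutralization; an average
venom yield over the venom mass one vial neutralizes gives vials per bite.

Unit transforms for the enzymatic and local-damage assays (azocoll
collagenolysis, PLA2 on NOBA, minimum hemorrhagic dose, paw edema) live
here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ProbitFit",
    "PotencyResult",
    "probit_fit",
    "probit_loglik",
    "potency_from_ed50",
    "percent_neutralizing",
    "vials_per_bite",
    "mhd",
    "edema_percent",
    "azocoll_activity",
    "pla2_activity",
]

DOSE_COLUMNS = ["dose", "n_subjects", "n_responders"]

AZOCOLL_UNIT_DELTA_A = 0.003     # delta A540 defining one unit of activity
NOBA_NMOL_PER_001_A = 25.8       # nmol chromophore per 0.01 A425


@dataclass
class ProbitFit:
    """Probit regression summary on the log10(dose) scale."""

    slope: float
    intercept: float
    median: float               # LD50 or ED50, original dose units
    ci95: tuple[float, float]
    converged: bool
    log_likelihood: float = float("nan")


def _validate_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(DOSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    t = table.copy()
    if (t["dose"] <= 0).any():
        raise ValueError("doses must be > 0")
    if (t["n_subjects"] <= 0).any():
        raise ValueError("group sizes must be > 0")
    bad = (t["n_responders"] < 0) | (t["n_responders"] > t["n_subjects"])
    if bad.any():
        raise ValueError("responders must lie in [0, n_subjects]")
    return t.sort_values("dose").reset_index(drop=True)


def probit_loglik(
    intercept: float, slope: float, table: pd.DataFrame
) -> float:
    """Binomial log-likelihood of a (intercept, slope) probit model.

    Response probability Phi(intercept + slope·log10(dose)); used by tests
    as a grid-search oracle against the ML fit.
    """
    t = _validate_dose_table(table)
    logd = np.log10(t["dose"].to_numpy(dtype=float))
    p = sps.norm.cdf(intercept + slope * logd)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    k = t["n_responders"].to_numpy(dtype=float)
    n = t["n_subjects"].to_numpy(dtype=float)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def _separation_fallback(t: pd.DataFrame) -> ProbitFit:
    """Median as the geometric mean of the doses bracketing the 0->1 jump."""
    frac = t["n_responders"] / t["n_subjects"]
    below = t.loc[frac == 0, "dose"]
    above = t.loc[frac == 1, "dose"]
    if below.empty or above.empty:
        raise ValueError("degenerate dose table: responses all 0 or all n")
    lo, hi = float(below.max()), float(above.min())
    med = float(np.sqrt(lo * hi))
    return ProbitFit(
        slope=float("inf"),
        intercept=float("-inf"),
        median=med,
        ci95=(lo, hi),
        converged=False,
    )


def probit_fit(table: pd.DataFrame) -> ProbitFit:
    """Fit a quantal dose–response by ML probit regression on log10(dose).

    Returns the median dose 10^(-intercept/slope) with delta-method 95%
    confidence limits computed on the log10 scale.  Tables with complete
    separation (a pure 0 -> n step with no partial-response group) cannot
    support an ML fit; the median is then the geometric mean of the doses
    bracketing the jump and ``converged`` is False.
    """
    t = _validate_dose_table(table)
    if t["dose"].nunique() < 2:
        raise ValueError("need at least 2 distinct doses")
    frac = t["n_responders"] / t["n_subjects"]
    if (frac == 0).all() or (frac == 1).all():
        raise ValueError("responses all zero or all maximal: median undefined")
    informative = ((frac > 0) & (frac < 1)).sum()
    if informative < 2 and set(np.unique(frac)) <= {0.0, 1.0}:
        return _separation_fallback(t)

    logd = np.log10(t["dose"].to_numpy(dtype=float))
    X = sm.add_constant(logd)
    endog = np.column_stack(
        [
            t["n_responders"].to_numpy(dtype=float),
            (t["n_subjects"] - t["n_responders"]).to_numpy(dtype=float),
        ]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial(sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception:
            return _separation_fallback(t)
    b0, b1 = res.params
    if not np.isfinite([b0, b1]).all() or b1 <= 0:
        return _separation_fallback(t)
    log_median = -b0 / b1
    # delta method: g(b) = -b0/b1, grad = (-1/b1, b0/b1^2)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ res.cov_params() @ grad)
    se = np.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.975)
    ci = (10.0 ** (log_median - z * se), 10.0 ** (log_median + z * se))
    return ProbitFit(
        slope=float(b1),
        intercept=float(b0),
        median=float(10.0**log_median),
        ci95=ci,
        converged=bool(res.converged),
        log_likelihood=float(res.llf),
    )


@dataclass
class PotencyResult:
    """Neutralization summary: ED50 -> potency -> antibodies -> vials."""

    ed50: float
    ed50_ci95: tuple[float, float]
    n_challenge: int
    potency: float
    potency_ci95: tuple[float, float]
    percent_neutralizing: float | None = None
    vials_per_bite: float | None = None


def potency_from_ed50(ed50: float, n_challenge: int) -> float:
    """P = ED50·(n-1)/n for a challenge of n LD50s.

    At the 50% survival endpoint one of the n LD50s remains unneutralized,
    so only (n-1)/n of the challenge is actually bound per unit antivenom.
    Equivalently P = [(n-1)/ED50]·LD50 when the ED50 is expressed in
    antivenom per LD50.
    """
    if ed50 <= 0:
        raise ValueError("ED50 must be > 0")
    if n_challenge <= 1:
        raise ValueError("challenge must exceed 1 LD50")
    return ed50 * (n_challenge - 1) / n_challenge


def percent_neutralizing(potency: float, max_bind: float) -> float:
    """100·P/MaxBind — the share of binding antibodies that neutralize.

    Values above 100% are expected when neutralizing a lethal subset of
    toxins suffices to abrogate whole-venom lethality.
    """
    if max_bind <= 0:
        raise ValueError("MaxBind must be > 0")
    return 100.0 * potency / max_bind


def vials_per_bite(
    venom_yield_mg: float, potency: float, fab2_g_per_vial: float
) -> float:
    """Vials needed for an average bite: yield / (P x g F(ab')2 per vial)."""
    if min(venom_yield_mg, potency, fab2_g_per_vial) <= 0:
        raise ValueError("all inputs must be > 0")
    return venom_yield_mg / (potency * fab2_g_per_vial)


def mhd(dose_area: list[tuple[float, float]]) -> float:
    """Minimum hemorrhagic dose: venom amount giving a 1 cm² lesion.

    Hemorrhagic area is regressed on log10(dose) by least squares and the
    line inverted at area = 1 cm²; with exactly two points this is the
    two-point log-linear interpolation.  Doses outside the observed range
    are extrapolations and raise a warning.
    """
    if len(dose_area) < 2:
        raise ValueError("need at least 2 (dose, area) points")
    d = np.asarray([p[0] for p in dose_area], dtype=float)
    a = np.asarray([p[1] for p in dose_area], dtype=float)
    if (d <= 0).any():
        raise ValueError("doses must be > 0")
    if np.allclose(a, a[0]):
        if np.isclose(a[0], 1.0):
            raise ValueError("flat response at 1 cm2: MHD indeterminate")
        raise ValueError("flat dose-area response: MHD undefined")
    beta, alpha = np.polyfit(np.log10(d), a, 1)
    if beta == 0:
        raise ValueError("zero slope: MHD undefined")
    mhd_val = float(10.0 ** ((1.0 - alpha) / beta))
    if not (a.min() <= 1.0 <= a.max()):
        warnings.warn(
            "1 cm2 outside observed areas: MHD is an extrapolation",
            stacklevel=2,
        )
    return mhd_val


def edema_percent(
    test_thickness: np.ndarray | list[float],
    control_thickness: np.ndarray | list[float],
) -> np.ndarray:
    """Percentage increase of treated-paw over control-paw thickness.

    Paired timepoints; negative values (thinner than control) are reported
    as-is.
    """
    t = np.asarray(test_thickness, dtype=float)
    c = np.asarray(control_thickness, dtype=float)
    if t.shape != c.shape:
        raise ValueError("test and control series must align timepoint-wise")
    if (c <= 0).any():
        raise ValueError("control thickness must be > 0")
    return 100.0 * (t - c) / c


def azocoll_activity(
    delta_a540: float, minutes: float, venom_mg: float
) -> float:
    """Collagenolytic activity, U/min/mg (one unit = delta A540 of 0.003)."""
    if minutes <= 0 or venom_mg <= 0:
        raise ValueError("time and venom mass must be > 0")
    return (delta_a540 / AZOCOLL_UNIT_DELTA_A) / minutes / venom_mg


def pla2_activity(delta_a425: float, minutes: float, venom_mg: float) -> float:
    """PLA2 activity on NOBA, nmol chromophore/min/mg.

    0.01 absorbance units at 425 nm correspond to 25.8 nmol of released
    chromophore.
    """
    if minutes <= 0 or venom_mg <= 0:
        raise ValueError("time and venom mass must be > 0")
    return (delta_a425 / 0.01) * NOBA_NMOL_PER_001_A / minutes / venom_mg
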