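"""Third-generation antivenomics (3GA): immunocapture quantification.

A 3GA experiment incubates increasing amounts of crude venom (here
100–3600 μg) with affinity columns carrying a fixed mass of immobilized
antivenom F(ab')2 (7 mg).  For each RP-HPLC toxin fraction, the retained
(Ri) and non-retained (NRi) chromatogram areas give the percentage of that
toxin captured, %Ri = 100·Ri/(Ri+NRi); combined with the toxin's share of
the venom proteome and the venom amount loaded, this yields the captured
mass in μg.  Captured mass versus venom load saturates; its maximum per
toxin, summed over toxins and divided by the antivenom on the column, is
the antivenom's maximal binding capacity (MaxBind, mg venom per g
antivenom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImmunoaffinitySeries",
    "SaturationFit",
    "BindingCapacity",
    "retained_fraction",
    "control_correct",
    "immunocaptured_mass",
    "fit_saturation",
    "max_binding_capacity",
    "capacity_units",
    "coupled_concentration",
    "analyze_series",
]

SERIES_COLUMNS = [
    "toxin_id",
    "venom_amount_ug",
    "retained_area",
    "nonretained_area",
    "control_retained_pct",
]


def retained_fraction(ri: float, nri: float) -> float:
    """%Ri = 100·Ri/(Ri+NRi) — the immunocaptured share of one toxin."""
    if ri < 0 or nri < 0:
        raise ValueError("areas must be non-negative")
    total = ri + nri
    if total <= 0:
        raise ValueError("Ri + NRi must be > 0")
    return 100.0 * ri / total


def control_correct(percent_retained: float, control_retained: float) -> float:
    """Subtract nonspecific (mock/naive-IgG column) retention, floored at 0."""
    for v in (percent_retained, control_retained):
        if not 0 <= v <= 100:
            raise ValueError(f"percentage out of [0, 100]: {v}")
    return max(0.0, percent_retained - control_retained)


def immunocaptured_mass(
    percent_retained: float, toxin_share: float, venom_amount: float
) -> float:
    """μg of one toxin captured by the column.

    (%Ri/100) x (toxin's % of the venom proteome / 100) x μg venom loaded.
    """
    if min(percent_retained, toxin_share, venom_amount) < 0:
        raise ValueError("inputs must be non-negative")
    if percent_retained > 100 or toxin_share > 100:
        raise ValueError("percentages must be <= 100")
    return (percent_retained / 100.0) * (toxin_share / 100.0) * venom_amount


@dataclass
class SaturationFit:
    """Result of the quadratic saturation extrapolation for one toxin."""

    max_captured_ug: float      # modeled maximum used downstream
    raw_max_ug: float           # largest observed captured mass
    coefficients: tuple[float, float, float]  # (a, b, c) of a x^2 + b x + c
    vertex_x: float | None      # venom load at the modeled maximum, if any
    saturated: bool             # True if a concave vertex in the trusted range


def fit_saturation(
    points: list[tuple[float, float]], extrapolation_factor: float = 2.0
) -> SaturationFit:
    """Estimate a toxin's maximal captured mass from a dose series.

    Captured mass vs venom load is fitted with a least-squares degree-2
    polynomial.  If the parabola is concave (a < 0) and its vertex lies in
    (0, ``extrapolation_factor`` x max load], the vertex value is the
    modeled maximum and the series is flagged saturated.  Otherwise — an
    upward-opening or still-rising fit has no data-supported maximum — the
    largest observed captured mass is reported and the flag is False.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dose points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct venom amounts")
    a, b, c = np.polyfit(x, y, 2)
    raw_max = float(np.max(y))
    vertex_x = None
    modeled = raw_max
    saturated = False
    if a < 0:
        xv = -b / (2.0 * a)
        if 0 < xv <= extrapolation_factor * float(np.max(x)):
            vertex_x = float(xv)
            modeled = float(a * xv * xv + b * xv + c)
            saturated = True
    return SaturationFit(
        max_captured_ug=max(0.0, modeled),
        raw_max_ug=raw_max,
        coefficients=(float(a), float(b), float(c)),
        vertex_x=vertex_x,
        saturated=saturated,
    )


def max_binding_capacity(
    per_toxin_max_ug: dict[str, float] | list[float],
    antivenom_mass_mg: float,
) -> float:
    """MaxBind, mg venom / g antivenom.

    Sum of per-toxin maximal captured masses (μg) over the antivenom mass
    on the column (mg): μg/mg == mg/g.
    """
    if antivenom_mass_mg <= 0:
        raise ValueError("antivenom mass on column must be > 0")
    values = (
        list(per_toxin_max_ug.values())
        if isinstance(per_toxin_max_ug, dict)
        else list(per_toxin_max_ug)
    )
    if any(v < 0 for v in values):
        raise ValueError("per-toxin maxima must be non-negative")
    return float(sum(values)) / antivenom_mass_mg


def capacity_units(
    max_bind_mg_per_g: float,
    fab2_g_per_L: float,
    fab2_g_per_vial: float,
) -> dict[str, float]:
    """Convert MaxBind to per-millilitre and per-vial figures.

    mg venom/mL antivenom = MaxBind (mg/g) x concentration (g/L) / 1000;
    mg venom/vial = MaxBind x g F(ab')2 per vial.
    """
    if max_bind_mg_per_g < 0:
        raise ValueError("MaxBind must be >= 0")
    if fab2_g_per_L <= 0 or fab2_g_per_vial <= 0:
        raise ValueError("antivenom constants must be > 0")
    return {
        "mg_venom_per_mL": max_bind_mg_per_g * fab2_g_per_L / 1000.0,
        "mg_venom_per_vial": max_bind_mg_per_g * fab2_g_per_vial,
    }


def coupled_concentration(
    a280_before: float,
    a280_after: float,
    volume_ratio: float = 1.0,
    extinction: float = 1.36,
) -> float:
    """Antivenom coupled to the matrix from the A280 drop, mg/mL.

    Uses the F(ab')2 0.1% extinction coefficient (1.36 (mg/mL)^-1 cm^-1,
    1 cm path).
    """
    if extinction <= 0:
        raise ValueError("extinction coefficient must be > 0")
    if a280_after < 0 or a280_before < a280_after:
        raise ValueError("A280 must not increase on coupling")
    return (a280_before - a280_after) * volume_ratio / extinction


@dataclass
class ImmunoaffinitySeries:
    """One 3GA experiment: dose series of Ri/NRi areas for each toxin."""

    observations: pd.DataFrame          # SERIES_COLUMNS, long format
    proteome_shares: dict[str, float]   # toxin_id -> % of venom proteome
    antivenom_mass_mg: float = 7.0

    def __post_init__(self) -> None:
        missing = set(SERIES_COLUMNS) - set(self.observations.columns)
        if missing:
            raise ValueError(f"series table missing columns: {sorted(missing)}")
        obs = self.observations
        if ((obs["retained_area"] < 0) | (obs["nonretained_area"] < 0)).any():
            raise ValueError("negative chromatogram areas")
        if any(s < 0 for s in self.proteome_shares.values()):
            raise ValueError("negative proteome shares")
        for toxin, grp in obs.groupby("toxin_id"):
            x = grp["venom_amount_ug"].to_numpy(dtype=float)
            if np.any(np.diff(np.sort(x)) <= 0):
                raise ValueError(f"duplicate venom amounts for toxin {toxin!r}")


@dataclass
class BindingCapacity:
    """MaxBind with per-toxin detail and derived dosing units."""

    max_bind_mg_per_g: float
    mg_venom_per_mL: float
    mg_venom_per_vial: float
    per_toxin: dict[str, SaturationFit] = field(default_factory=dict)


def analyze_series(
    series: ImmunoaffinitySeries,
    fab2_g_per_L: float = 46.45,
    fab2_g_per_vial: float = 0.4645,
    control_corrected: bool = True,
) -> BindingCapacity:
    """Full 3GA quantification of one venom/antivenom pair.

    Per toxin: %Ri at each load (optionally minus the mock-column control),
    captured mass, quadratic saturation extrapolation; then MaxBind as the
    summed maxima over the antivenom on the column, plus per-mL and
    per-vial conversions.  Toxins with fewer than 3 usable doses fall back
    to their largest observed captured mass (flagged unsaturated).
    """
    fits: dict[str, SaturationFit] = {}
    for toxin, grp in series.observations.groupby("toxin_id", sort=True):
        share = series.proteome_shares.get(str(toxin))
        if share is None:
            raise ValueError(f"no proteome share for toxin {toxin!r}")
        pts = []
        for row in grp.sort_values("venom_amount_ug").itertuples():
            pct = retained_fraction(row.retained_area, row.nonretained_area)
            if control_corrected:
                pct = control_correct(pct, row.control_retained_pct)
            pts.append(
                (row.venom_amount_ug,
                 immunocaptured_mass(pct, share, row.venom_amount_ug))
            )
        if len(pts) >= 3:
            fits[str(toxin)] = fit_saturation(pts)
        else:
            raw = max(p[1] for p in pts)
            fits[str(toxin)] = SaturationFit(raw, raw, (0.0, 0.0, raw), None, False)
    max_bind = max_binding_capacity(
        {t: f.max_captured_ug for t, f in fits.items()},
        series.antivenom_mass_mg,
    )
    units = capacity_units(max_bind, fab2_g_per_L, fab2_g_per_vial)
    return BindingCapacity(
        max_bind_mg_per_g=max_bind,
        mg_venom_per_mL=units["mg_venom_per_mL"],
        mg_venom_per_vial=units["mg_venom_per_vial"],
        per_toxin=fits,
    )
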