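"""Family-level venom composition: peak areas to mass % and molar %.

Reversed-phase HPLC of a crude venom resolves it into peaks; the area of a
peak at 215 nm is proportional to the weight of protein it contains, so the
summed area share of a toxin family is its relative abundance in g per
100 g of venom.  Dividing a family's mass percentage by a representative
molecular mass converts it to millimoles per 100 g of venom ("molar %"),
the scale on which stoichiometric arguments — e.g. the excess of the
tripeptide metalloproteinase inhibitor SVMPi over its SVMP targets — are
made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToxinFamily",
    "VenomComposition",
    "BandAllocation",
    "Band",
    "integrate_peaks",
    "relative_abundance",
    "mass_to_molar",
    "molar_to_mass",
    "molar_ratio",
    "molecule_fraction",
    "classify_dichotomy",
    "allocate_band_abundance",
    "round_half_away",
]

UNASSIGNED = "unassigned"

PEAK_TABLE_COLUMNS = ["fraction_id", "retention_time_min", "area", "family"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as in the published tables.

    Python's built-in ``round`` uses banker's rounding; printed-value
    comparisons in this package use the half-away-from-zero convention.
    """
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class ToxinFamily:
    """A toxin class with a representative molecular mass in daltons."""

    name: str
    molecular_mass: float

    def __post_init__(self) -> None:
        if self.molecular_mass <= 0:
            raise ValueError(
                f"molecular mass of {self.name!r} must be > 0, "
                f"got {self.molecular_mass}"
            )


@dataclass
class VenomComposition:
    """Per-family relative abundance of one venom.

    ``mass_percent`` maps family name -> g/100 g venom; ``molar_percent``
    (mmoles per 100 g venom) is derived on construction for every family
    with a known molecular mass in ``registry``.
    """

    species: str
    mass_percent: dict[str, float]
    registry: Mapping[str, float]
    molar_percent: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for fam, mp in self.mass_percent.items():
            if mp < 0:
                raise ValueError(f"negative mass percent for {fam!r}: {mp}")
        total = sum(self.mass_percent.values())
        if total > 100 + 1e-6:
            raise ValueError(
                f"mass percentages sum to {total:.4f} > 100 for {self.species!r}"
            )
        self.molar_percent = {
            fam: mass_to_molar(mp, self.registry[fam])
            for fam, mp in self.mass_percent.items()
            if fam in self.registry
        }

    def get(self, family: str) -> float:
        return self.mass_percent.get(family, 0.0)

    def get_molar(self, family: str) -> float:
        return self.molar_percent.get(family, 0.0)


def integrate_peaks(
    trace: tuple[Sequence[float], Sequence[float]],
    bounds: Sequence[tuple[float, float, float]],
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Integrate a chromatographic trace over peak windows.

    Parameters
    ----------
    trace
        ``(times, signal)`` with strictly increasing times (minutes).
    bounds
        Per peak: ``(start, end, baseline)``.  The net area is the
        trapezoidal integral of ``signal - baseline`` over [start, end],
        clamped at zero.  Windows must not overlap.
    families
        Optional family label per bound; defaults to ``"unassigned"``.

    Returns
    -------
    A peak table with columns ``fraction_id, retention_time_min, area,
    family`` — one row per bound, ordered by start time.
    """
    times = np.asarray(trace[0], dtype=float)
    signal = np.asarray(trace[1], dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    if times.size != signal.size:
        raise ValueError("times and signal differ in length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("trace times must be strictly increasing")

    ordered = sorted(range(len(bounds)), key=lambda i: bounds[i][0])
    for a, b in zip(ordered, ordered[1:]):
        if bounds[a][1] > bounds[b][0] + 1e-12:
            raise ValueError(
                f"overlapping integration windows {bounds[a][:2]} and {bounds[b][:2]}"
            )
    if families is None:
        families = [UNASSIGNED] * len(bounds)
    elif len(families) != len(bounds):
        raise ValueError("one family label per bound required")

    rows = []
    for k in ordered:
        start, end, baseline = bounds[k]
        if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
            raise ValueError(f"window ({start}, {end}) outside trace range")
        mask = (times >= start) & (times <= end)
        t, s = times[mask], signal[mask] - baseline
        area = max(0.0, float(np.trapezoid(s, t))) if t.size >= 2 else 0.0
        rows.append(
            {
                "fraction_id": f"F{k + 1}",
                "retention_time_min": 0.5 * (start + end),
                "area": area,
                "family": families[k],
            }
        )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def relative_abundance(peaks: pd.DataFrame) -> dict[str, float]:
    """Family-level mass percentages from a peak table.

    Each family's abundance is 100 x (sum of its peak areas) / (total peak
    area).  Rows labelled ``"unassigned"`` count in the denominator and are
    reported under their own key, so the output always sums to 100.
    """
    missing = set(PEAK_TABLE_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["area"] < 0).any():
        raise ValueError("negative peak areas")
    total = float(peaks["area"].sum())
    if total <= 0:
        raise ValueError("total peak area is zero")
    fam = peaks["family"].fillna(UNASSIGNED)
    shares = peaks.groupby(fam)["area"].sum() * (100.0 / total)
    return {str(k): float(v) for k, v in shares.items()}


def mass_to_molar(mass_percent: float, molecular_mass: float) -> float:
    """g/100 g venom -> mmoles per 100 g venom.

    molar% = 1000 x mass% / M, with M in daltons: a family at m g per 100 g
    venom contributes m/M moles = 1000 m/M millimoles per 100 g.
    """
    if molecular_mass <= 0:
        raise ValueError(f"molecular mass must be > 0, got {molecular_mass}")
    if mass_percent < 0:
        raise ValueError(f"mass percent must be >= 0, got {mass_percent}")
    return 1000.0 * mass_percent / molecular_mass


def molar_to_mass(molar_percent: float, molecular_mass: float) -> float:
    """Inverse of :func:`mass_to_molar`."""
    if molecular_mass <= 0:
        raise ValueError(f"molecular mass must be > 0, got {molecular_mass}")
    return molar_percent * molecular_mass / 1000.0


def molar_ratio(
    composition: VenomComposition,
    numerator: Iterable[str],
    denominator: Iterable[str],
) -> float:
    """Ratio of summed molar abundances of two family sets."""
    num = sum(composition.get_molar(f) for f in numerator)
    den = sum(composition.get_molar(f) for f in denominator)
    if den <= 0:
        raise ValueError("denominator families have zero total molar abundance")
    return num / den


def molecule_fraction(composition: VenomComposition, family: str) -> float:
    """Percentage of all tabulated venom molecules belonging to one family.

    The denominator is restricted to families with a registered molecular
    mass (the tabulated classes); trace components without one cannot enter
    a molar sum.
    """
    if family not in composition.molar_percent:
        raise ValueError(f"family {family!r} absent from composition")
    total = sum(composition.molar_percent.values())
    if total <= 0:
        raise ValueError("total molar abundance is zero")
    return 100.0 * composition.molar_percent[family] / total


def classify_dichotomy(
    composition: VenomComposition,
    k49_negligible_molar: float = 0.05,
    k49_d49_high: float = 1.5,
    k49_d49_low: float = 0.67,
    low_piii_rescue: float | None = None,
) -> str:
    """Assign a venom to one of three PLA2 compositional patterns.

    * ``"I"``  — K49 phospholipase homologues dominate the D49 forms
      (K49/D49 molar ratio >= ``k49_d49_high``), typically with low
      PIII-SVMP content.
    * ``"II"`` — K49 absent or negligible (< ``k49_negligible_molar``
      mmoles %), D49 dominant.
    * ``"III"`` — comparable K49 and D49 levels.

    ``low_piii_rescue``, if given, promotes a borderline III to I when
    PIII-SVMP molar abundance is below the threshold and K49 exceeds D49 —
    venoms whose defining trait is high K49 with depressed PIII rather than
    an extreme K49/D49 ratio.
    """
    k49 = composition.get_molar("K49-PLA2")
    d49 = composition.get_molar("D49-PLA2")
    piii = composition.get_molar("PIII-SVMP")
    if k49 < k49_negligible_molar:
        return "II"
    if d49 <= 0:
        return "I"
    ratio = k49 / d49
    if ratio >= k49_d49_high:
        return "I"
    if low_piii_rescue is not None and ratio > 1.0 and piii < low_piii_rescue:
        return "I"
    if ratio >= k49_d49_low:
        return "III"
    # K49 present but clearly below D49: nearer the D49-dominant pattern.
    return "II"


@dataclass
class Band:
    """One electrophoretic band of a chromatographic fraction."""

    band_id: str
    densitometry_share: float
    # protein -> top-3 peptide-ion intensities (arbitrary units)
    ion_intensities: dict[str, tuple[float, ...]]


@dataclass
class BandAllocation:
    """Allocation of one fraction's chromatogram share to proteins.

    A fraction's percentage of the whole chromatogram is split across its
    SDS-PAGE bands by densitometry, and within a band across co-migrating
    proteins by the relative summed intensities of each protein's three
    most abundant peptide ions.
    """

    fraction_percent: float
    bands: list[Band]


def allocate_band_abundance(
    allocation: BandAllocation, share_tol: float = 1e-6
) -> dict[str, float]:
    """Split a fraction's chromatogram percentage down to proteins.

    Returns protein -> % of the whole chromatogram; the values sum to the
    fraction's percentage (conservation).
    """
    total_share = sum(b.densitometry_share for b in allocation.bands)
    if abs(total_share - 1.0) > max(share_tol, 1e-6):
        raise ValueError(
            f"densitometry shares sum to {total_share:.6f}, expected 1"
        )
    out: dict[str, float] = {}
    for band in allocation.bands:
        sums = {p: float(sum(v)) for p, v in band.ion_intensities.items()}
        if any(s < 0 for s in sums.values()):
            raise ValueError(f"negative ion intensity in band {band.band_id!r}")
        band_total = sum(sums.values())
        if band_total <= 0:
            if len(sums) == 1:
                # single protein: intensities are irrelevant
                sums = {next(iter(sums)): 1.0}
                band_total = 1.0
            else:
                raise ValueError(
                    f"band {band.band_id!r} has multiple proteins but zero "
                    "total ion intensity"
                )
        for protein, s in sums.items():
            pct = (
                allocation.fraction_percent
                * band.densitometry_share
                * s
                / band_total
            )
            out[protein] = out.get(protein, 0.0) + pct
    return out
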