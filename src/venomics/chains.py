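"""End-to-end analysis chains tying the modules into single reports.

Every report dict carries the configuration hash (and seed where
randomness is involved) so any number in it can be regenerated from the
command line alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd

from . import io
from .antivenomics import ImmunoaffinitySeries, analyze_series
from .bioassay import (
    PotencyResult,
    percent_neutralizing,
    potency_from_ed50,
    probit_fit,
    vials_per_bite,
)
from .composition import (
    VenomComposition,
    classify_dichotomy,
    molar_ratio,
    relative_abundance,
    round_half_away,
)
from .config import AnalysisConfig

__all__ = ["run_chain_composition", "run_chain_antivenom", "potency_chain"]

SVMP_FAMILIES = ("PI-SVMP", "PIII-SVMP")


def run_chain_composition(
    peak_csv: str | Path,
    config: AnalysisConfig | None = None,
    species: str = "unknown",
) -> dict[str, Any]:
    """Peak table -> mass %, molar %, SVMPi/SVMP ratio, dichotomy pattern."""
    config = config or AnalysisConfig()
    try:
        peaks = io.read_peak_table(peak_csv)
    except ValueError as exc:
        raise ValueError(f"composition chain: {exc}") from exc
    shares = relative_abundance(peaks)
    unassigned = shares.pop("unassigned", 0.0)
    comp = VenomComposition(
        species=species,
        mass_percent=shares,
        registry=config.family_registry,
    )
    th = config.dichotomy
    report: dict[str, Any] = {
        "species": species,
        "mass_percent": {f: v for f, v in shares.items()},
        "unassigned_percent": unassigned,
        "molar_percent": dict(comp.molar_percent),
        "pattern": classify_dichotomy(
            comp,
            k49_negligible_molar=th.k49_negligible_molar,
            k49_d49_high=th.k49_d49_high,
            k49_d49_low=th.k49_d49_low,
        ),
        "config_hash": config.config_hash(),
    }
    try:
        report["svmpi_svmp_molar_ratio"] = molar_ratio(
            comp, ["SVMPi"], list(SVMP_FAMILIES)
        )
    except ValueError:
        report["svmpi_svmp_molar_ratio"] = None
    return report


def potency_chain(
    ed50: float,
    ed50_ci95: tuple[float, float],
    n_challenge: int,
    max_bind: float | None = None,
    venom_yield_mg: float | None = None,
    fab2_g_per_vial: float = 0.4645,
) -> PotencyResult:
    """ED50 -> potency (CI propagated elementwise) -> % neutralizing -> vials."""
    p = potency_from_ed50(ed50, n_challenge)
    ci = tuple(potency_from_ed50(v, n_challenge) for v in ed50_ci95)
    res = PotencyResult(
        ed50=ed50,
        ed50_ci95=tuple(ed50_ci95),
        n_challenge=n_challenge,
        potency=p,
        potency_ci95=ci,  # type: ignore[arg-type]
    )
    if max_bind is not None:
        res.percent_neutralizing = percent_neutralizing(p, max_bind)
    if venom_yield_mg is not None:
        res.vials_per_bite = vials_per_bite(venom_yield_mg, p, fab2_g_per_vial)
    return res


def run_chain_antivenom(
    antivenomics_csv: str | Path,
    dose_csv: str | Path | None = None,
    config: AnalysisConfig | None = None,
    proteome_shares: dict[str, float] | None = None,
    venom_yield_mg: float | None = None,
    control_corrected: bool = True,
) -> dict[str, Any]:
    """Immunocapture series (+ optional neutralization assay) -> full report.

    MaxBind in mg/g, mg/mL and mg/vial from the 3GA series; if a
    neutralization dose table is given, ED50 with CI, potency with CI,
    percentage of neutralizing antibodies and vials per average bite.
    """
    config = config or AnalysisConfig()
    try:
        obs = io.read_antivenomics(antivenomics_csv)
    except ValueError as exc:
        raise ValueError(f"antivenomics stage: {exc}") from exc
    if proteome_shares is None:
        raise ValueError("antivenomics stage: proteome shares are required")
    series = ImmunoaffinitySeries(
        observations=obs,
        proteome_shares=proteome_shares,
        antivenom_mass_mg=config.antivenom.mass_on_column_mg,
    )
    cap = analyze_series(
        series,
        fab2_g_per_L=config.antivenom.fab2_g_per_L,
        fab2_g_per_vial=config.antivenom.fab2_g_per_vial,
        control_corrected=control_corrected,
    )
    nd = config.rounding
    report: dict[str, Any] = {
        "max_bind_mg_per_g": cap.max_bind_mg_per_g,
        "mg_venom_per_mL": round_half_away(cap.mg_venom_per_mL, nd["capacity"]),
        "mg_venom_per_vial": round_half_away(cap.mg_venom_per_vial, nd["capacity"]),
        "per_toxin": {
            t: {
                "modeled_max_ug": f.max_captured_ug,
                "raw_max_ug": f.raw_max_ug,
                "saturated": f.saturated,
            }
            for t, f in cap.per_toxin.items()
        },
        "config_hash": config.config_hash(),
    }
    if dose_csv is not None:
        try:
            doses = io.read_dose_table(dose_csv)
        except ValueError as exc:
            raise ValueError(f"neutralization stage: {exc}") from exc
        fit = probit_fit(doses)
        pot = potency_chain(
            fit.median,
            fit.ci95,
            config.n_challenge,
            max_bind=cap.max_bind_mg_per_g,
            venom_yield_mg=venom_yield_mg,
            fab2_g_per_vial=config.antivenom.fab2_g_per_vial,
        )
        report.update(
            {
                "ed50": fit.median,
                "ed50_ci95": list(fit.ci95),
                "ed50_converged": fit.converged,
                "potency": round_half_away(pot.potency, nd["potency"]),
                "potency_ci95": [
                    round_half_away(v, nd["potency"]) for v in pot.potency_ci95
                ],
                "percent_neutralizing": round_half_away(
                    pot.percent_neutralizing, nd["percent_neutralizing"]
                )
                if pot.percent_neutralizing is not None
                else None,
                "vials_per_bite": round_half_away(pot.vials_per_bite, nd["vials"])
                if pot.vials_per_bite is not None
                else None,
            }
        )
    return report


def composition_table(
    compositions: list[VenomComposition],
) -> pd.DataFrame:
    """Long-format composition table (species, family, mass %, molar %)."""
    rows = []
    for comp in compositions:
        for fam, mp in comp.mass_percent.items():
            rows.append(
                {
                    "species": comp.species,
                    "family": fam,
                    "mass_percent": mp,
                    "molar_percent": comp.molar_percent.get(fam),
                }
            )
    return pd.DataFrame(rows)
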