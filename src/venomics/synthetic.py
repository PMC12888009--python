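"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of a :class:`GeneratorConfig` and the
seed inside it: rerunning with the same config yields identical output.
The generators emulate the statistical structure the analysis assumes —
per-specimen venom compositions scattered around species templates with an
anticorrelated K49-PLA2/PIII-SVMP perturbation, Gaussian-peak RP-HPLC
chromatograms, Langmuir-saturating immunocapture dose series, probit
dose–mortality tables, and log-linear hemorrhagic-area curves — so every
stage of the pipeline can be exercised against a known ground truth.

Default design parameters copy the study conditions: lethality doses
23–230 μg in groups of 5, immunocapture loads 100–3600 μg on 7 mg of
antivenom, hemorrhage doses 1.25–15 μg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .antivenomics import ImmunoaffinitySeries
from .composition import PEAK_TABLE_COLUMNS, VenomComposition

__all__ = [
    "GeneratorConfig",
    "DEFAULT_ELUTION_ORDER",
    "default_elution_template",
    "default_langmuir_truth",
    "gen_compositions",
    "gen_chromatogram",
    "gen_binding_series",
    "gen_lethality",
    "gen_hemorrhage",
]

# Qualitative RP-HPLC elution order of the toxin families (early -> late).
DEFAULT_ELUTION_ORDER: tuple[str, ...] = (
    "SVMPi", "DISI", "BPP", "K49-PLA2", "CRISP", "D49-PLA2",
    "SVSP", "CTL", "LAAO", "PI-SVMP", "PIII-SVMP",
)

LETHALITY_DOSES_UG = (23.0, 46.0, 69.0, 115.0, 161.0, 230.0)
BINDING_DOSES_UG = (100.0, 300.0, 600.0, 1200.0, 1800.0, 2700.0, 3600.0)
HEMORRHAGE_DOSES_UG = (1.25, 2.5, 5.0, 7.5, 10.0, 15.0)


def default_elution_template(
    start_min: float = 8.0, spacing_min: float = 6.0
) -> dict[str, float]:
    """Evenly spread retention times (minutes) in the canonical order."""
    return {
        fam: start_min + i * spacing_min
        for i, fam in enumerate(DEFAULT_ELUTION_ORDER)
    }


def default_langmuir_truth(
    species: str = "mattogrossensis",
    bmax_per_share: float = 8.0,
    kd_ug: float = 25.0,
) -> dict[str, dict[str, float]]:
    """Per-toxin Langmuir truth scaled to a species' proteome shares.

    Bmax proportional to the family's proteome share (an antivenom raised
    against whole venoms sees abundant toxins more), one shared apparent
    dissociation mass; totals land on the observed MaxBind scale (~650 μg
    on a 7 mg column).
    """
    shares = reference.MASS_PERCENT[species]
    return {
        fam: {"bmax_ug": bmax_per_share * share, "kd_ug": kd_ug}
        for fam, share in shares.items()
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study's defaults."""

    seed: int = 0
    species_templates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            sp: dict(v) for sp, v in reference.MASS_PERCENT.items()
        }
    )
    registry: dict[str, float] = field(
        default_factory=lambda: dict(reference.FAMILY_MASSES_DA)
    )
    composition_cv: float = 0.15
    binding_cv: float = 0.03
    area_cv: float = 0.0
    k49_piii_rho: float = -0.7
    # probit truths: dose units match the assay (μg venom; mg V/g AV)
    lethality_median: float = 70.0
    lethality_slope: float = 4.0
    neutralization_median: float = 180.0
    neutralization_slope: float = 4.0
    langmuir_truth: dict[str, dict[str, float]] = field(
        default_factory=default_langmuir_truth
    )
    antivenom_mass_mg: float = reference.ANTIVENOM_MG_ON_COLUMN
    hemorrhage_beta: float = 0.8
    hemorrhage_mhd: float = 3.0
    hemorrhage_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for cv in (self.composition_cv, self.binding_cv, self.area_cv):
            if cv < 0:
                raise ValueError("noise CVs must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(stream)))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size=None, z: np.ndarray | None = None
):
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    if z is None:
        z = rng.standard_normal(size)
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def gen_compositions(
    config: GeneratorConfig, n_per_species: int = 5
) -> tuple[pd.DataFrame, list[VenomComposition]]:
    """Per-specimen compositions around the species templates.

    Family abundances get multiplicative lognormal noise (CV
    ``composition_cv``) and are renormalized to the template's total, so
    each specimen remains a valid composition.  The K49-PLA2 and PIII-SVMP
    perturbations are drawn from a bivariate normal with correlation
    ``k49_piii_rho`` (default -0.7), emulating the inverse relationship
    between the two families across the clade.

    Returns an observation matrix (specimen_id, species, per-family molar
    abundances) and the composition objects.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    rho = config.k49_piii_rho
    if not -1 < rho < 1:
        raise ValueError(f"correlation must lie in (-1, 1), got {rho}")
    rng = config.rng(stream=1)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    rows = []
    comps: list[VenomComposition] = []
    for species in sorted(config.species_templates):
        template = config.species_templates[species]
        total = sum(template.values())
        for i in range(n_per_species):
            z_pair = chol @ rng.standard_normal(2)
            mass = {}
            for fam, mp in template.items():
                if fam == "K49-PLA2":
                    f = _lognormal_factor(rng, config.composition_cv, z=z_pair[0])
                elif fam == "PIII-SVMP":
                    f = _lognormal_factor(rng, config.composition_cv, z=z_pair[1])
                else:
                    f = _lognormal_factor(
                        rng, config.composition_cv, z=rng.standard_normal()
                    )
                mass[fam] = mp * float(f)
            scale = total / sum(mass.values())
            mass = {fam: v * scale for fam, v in mass.items()}
            comp = VenomComposition(
                species=species, mass_percent=mass, registry=config.registry
            )
            comps.append(comp)
            row = {
                "specimen_id": f"{species}-{i + 1:02d}",
                "species": species,
            }
            for fam in config.registry:
                row[f"{fam}_molar"] = comp.get_molar(fam)
            rows.append(row)
    return pd.DataFrame(rows), comps


def gen_chromatogram(
    composition: VenomComposition,
    elution_template: dict[str, float] | None = None,
    peak_sigma_min: float = 0.6,
    time_step_min: float = 0.02,
    area_cv: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """A synthetic RP-HPLC trace whose peak areas encode the composition.

    One Gaussian peak per family, centred at the template retention time,
    with area equal to the family's mass percentage (optionally jittered by
    ``area_cv``).  Returns ``(times, signal), bounds, families, truth`` —
    bounds are ±4 sigma windows with zero baseline, and ``truth`` is the
    peak table of exact areas, so ``integrate_peaks`` followed by
    ``relative_abundance`` closes the loop on the composition.
    """
    if peak_sigma_min <= 0:
        raise ValueError("peak width must be > 0")
    template = elution_template or default_elution_template()
    unknown = set(composition.mass_percent) - set(template)
    if unknown:
        raise ValueError(f"families missing from elution template: {sorted(unknown)}")
    fams = [f for f in template if f in composition.mass_percent]
    centers = np.array([template[f] for f in fams])
    areas = np.array([composition.mass_percent[f] for f in fams], dtype=float)
    if area_cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        areas = areas * _lognormal_factor(rng, area_cv, size=areas.size)

    t0 = centers.min() - 6 * peak_sigma_min
    t1 = centers.max() + 6 * peak_sigma_min
    times = np.arange(t0, t1 + time_step_min, time_step_min)
    signal = np.zeros_like(times)
    for c, a in zip(centers, areas):
        signal += (
            a / (peak_sigma_min * np.sqrt(2 * np.pi))
        ) * np.exp(-0.5 * ((times - c) / peak_sigma_min) ** 2)
    bounds = [
        (c - 4 * peak_sigma_min, c + 4 * peak_sigma_min, 0.0) for c in centers
    ]
    truth = pd.DataFrame(
        {
            "fraction_id": [f"F{i + 1}" for i in range(len(fams))],
            "retention_time_min": centers,
            "area": areas,
            "family": fams,
        },
        columns=PEAK_TABLE_COLUMNS,
    )
    return (times, signal), bounds, fams, truth


def gen_binding_series(
    config: GeneratorConfig,
    doses: tuple[float, ...] = BINDING_DOSES_UG,
    species: str = "mattogrossensis",
) -> tuple[ImmunoaffinitySeries, dict[str, float]]:
    """A Langmuir-saturating 3GA dose series with known per-toxin Bmax.

    For toxin i with proteome share s_i (% of venom), a venom load of x μg
    presents t = x·s_i/100 μg of the toxin; the captured mass is
    Bmax_i·t/(Kd_i + t), never exceeding t, with mean-one multiplicative
    lognormal noise of CV ``binding_cv``.  Retained/non-retained areas are
    back-computed so that ``retained_fraction`` and ``immunocaptured_mass``
    reproduce the captured mass exactly at zero noise.

    Returns the series plus toxin -> true Bmax (μg).
    """
    if len(doses) < 3 or min(doses) <= 0:
        raise ValueError("need >= 3 positive doses")
    shares = config.species_templates[species]
    rng = config.rng(stream=2)
    rows = []
    truth: dict[str, float] = {}
    for toxin in sorted(config.langmuir_truth):
        pars = config.langmuir_truth[toxin]
        bmax, kd = float(pars["bmax_ug"]), float(pars["kd_ug"])
        if bmax <= 0 or kd <= 0:
            raise ValueError(f"nonpositive Langmuir parameters for {toxin!r}")
        share = shares.get(toxin)
        if share is None:
            raise ValueError(f"toxin {toxin!r} absent from {species!r} proteome")
        truth[toxin] = bmax
        for x in doses:
            t = x * share / 100.0
            captured = bmax * t / (kd + t)
            captured *= float(_lognormal_factor(rng, config.binding_cv))
            captured = min(captured, t)
            rows.append(
                {
                    "toxin_id": toxin,
                    "venom_amount_ug": x,
                    "retained_area": captured,
                    "nonretained_area": t - captured,
                    "control_retained_pct": 0.0,
                }
            )
    series = ImmunoaffinitySeries(
        observations=pd.DataFrame(rows),
        proteome_shares={t: shares[t] for t in truth},
        antivenom_mass_mg=config.antivenom_mass_mg,
    )
    return series, truth


def gen_lethality(
    config: GeneratorConfig,
    doses: tuple[float, ...] = LETHALITY_DOSES_UG,
    n_per_group: int = 5,
    median: float | None = None,
    slope: float | None = None,
) -> pd.DataFrame:
    """A quantal lethality table from a probit dose–mortality truth.

    Deaths ~ Binomial(n, Phi(slope·(log10 d - log10 median))).
    """
    if min(doses) <= 0:
        raise ValueError("doses must be > 0")
    from scipy.stats import norm

    med = config.lethality_median if median is None else median
    slo = config.lethality_slope if slope is None else slope
    rng = config.rng(stream=3)
    d = np.asarray(doses, dtype=float)
    p = norm.cdf(slo * (np.log10(d) - np.log10(med)))
    deaths = rng.binomial(n_per_group, p)
    return pd.DataFrame(
        {"dose": d, "n_subjects": n_per_group, "n_responders": deaths}
    )


def gen_hemorrhage(
    config: GeneratorConfig, doses: tuple[float, ...] = HEMORRHAGE_DOSES_UG
) -> pd.DataFrame:
    """Hemorrhagic area vs dose: area = beta·log10(d) + alpha + eps.

    alpha is set from the configured true minimum hemorrhagic dose so the
    1 cm² crossing lies at ``hemorrhage_mhd``, inside the dose range by
    default.
    """
    if min(doses) <= 0:
        raise ValueError("doses must be > 0")
    beta = config.hemorrhage_beta
    alpha = 1.0 - beta * np.log10(config.hemorrhage_mhd)
    rng = config.rng(stream=4)
    d = np.asarray(doses, dtype=float)
    area = beta * np.log10(d) + alpha
    if config.hemorrhage_noise_sd > 0:
        area = area + rng.normal(0, config.hemorrhage_noise_sd, d.size)
    return pd.DataFrame({"dose_ug": d, "area_cm2": area})
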