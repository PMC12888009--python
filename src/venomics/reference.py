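"""Published reference tables for the *Bothrops neuwiedi* clade study.

These dictionaries hold the printed inputs of the analysis: toxin-family
molecular masses, per-species family abundances (g/100 g venom and the
published mmoles % they convert to), and the antivenomics / neutralization
summary values (binding capacities, ED50s with confidence intervals, venom
yields, antivenom constants).  They are data, not results: every derived
quantity in this package is recomputed from them at run time.

Species keys are bare epithets (``"mattogrossensis"`` etc.); all masses are
in daltons, abundances in g per 100 g whole venom, molar abundances in
millimoles per 100 g whole venom.
"""

from __future__ import annotations

# Representative molecular mass per toxin family (Da).
FAMILY_MASSES_DA: dict[str, float] = {
    "K49-PLA2": 1.40e4,
    "D49-PLA2": 1.40e4,
    "PI-SVMP": 2.30e4,
    "PIII-SVMP": 5.20e4,
    "SVSP": 2.80e4,
    "DISI": 7.50e3,
    "LAAO": 5.60e4,
    "CTL": 2.80e4,
    "CRISP": 2.30e4,
    "SVMPi": 444.4,
}

SPECIES: tuple[str, ...] = (
    "mattogrossensis",
    "diporus",
    "neuwiedi",
    "erythromelas",
    "pubescens",
    "pauloensis",
    "marmoratus",
)

# Family-level relative abundance, g toxin class / 100 g venom.
# A family absent from a species' proteome is simply omitted.
MASS_PERCENT: dict[str, dict[str, float]] = {
    "mattogrossensis": {
        "K49-PLA2": 7.5, "D49-PLA2": 6.4, "PI-SVMP": 19.8, "PIII-SVMP": 28.8,
        "SVSP": 5.7, "DISI": 3.2, "LAAO": 6.9, "CTL": 2.5, "CRISP": 0.6,
        "SVMPi": 12.8,
    },
    "diporus": {
        "K49-PLA2": 34.3, "D49-PLA2": 6.9, "PI-SVMP": 10.7, "PIII-SVMP": 14.3,
        "SVSP": 6.3, "DISI": 4.2, "LAAO": 4.4, "CTL": 2.9, "CRISP": 1.2,
        "SVMPi": 2.6,
    },
    "neuwiedi": {
        "K49-PLA2": 19.9, "D49-PLA2": 10.3, "PI-SVMP": 12.8, "PIII-SVMP": 9.7,
        "SVSP": 8.8, "DISI": 3.3, "LAAO": 8.1, "CTL": 2.4, "CRISP": 4.2,
        "SVMPi": 8.39,
    },
    "erythromelas": {
        "D49-PLA2": 26.5, "PI-SVMP": 12.1, "PIII-SVMP": 24.0,
        "SVSP": 6.0, "DISI": 3.4, "LAAO": 4.8, "CTL": 8.0, "CRISP": 0.4,
        "SVMPi": 6.5,
    },
    "pubescens": {
        "K49-PLA2": 32.6, "D49-PLA2": 2.3, "PI-SVMP": 12.2, "PIII-SVMP": 10.1,
        "SVSP": 13.5, "DISI": 4.7, "LAAO": 3.9, "CRISP": 5.00,
        "SVMPi": 6.16,
    },
    "pauloensis": {
        "K49-PLA2": 19.7, "D49-PLA2": 15.9, "PI-SVMP": 12.7, "PIII-SVMP": 9.3,
        "SVSP": 15.3, "DISI": 2.4, "LAAO": 5.3, "CRISP": 0.1,
        "SVMPi": 7.77,
    },
    "marmoratus": {
        "K49-PLA2": 10.7, "D49-PLA2": 9.2, "PI-SVMP": 18.1, "PIII-SVMP": 22.1,
        "SVSP": 16.1, "DISI": 2.8, "LAAO": 3.8, "CRISP": 2.8,
        "SVMPi": 8.25,
    },
}

# Published molar abundances (mmoles per 100 g venom) for the same cells.
# Used only as the regression oracle for the mass->molar conversion.
MOLAR_PERCENT_PUBLISHED: dict[str, dict[str, float]] = {
    "mattogrossensis": {
        "K49-PLA2": 0.536, "D49-PLA2": 0.457, "PI-SVMP": 0.861,
        "PIII-SVMP": 0.554, "SVSP": 0.204, "DISI": 0.427, "LAAO": 0.123,
        "CTL": 0.089, "CRISP": 0.026, "SVMPi": 28.803,
    },
    "diporus": {
        "K49-PLA2": 2.450, "D49-PLA2": 0.493, "PI-SVMP": 0.465,
        "PIII-SVMP": 0.275, "SVSP": 0.225, "DISI": 0.560, "LAAO": 0.079,
        "CTL": 0.104, "CRISP": 0.052, "SVMPi": 5.851,
    },
    "neuwiedi": {
        "K49-PLA2": 1.421, "D49-PLA2": 0.736, "PI-SVMP": 0.557,
        "PIII-SVMP": 0.187, "SVSP": 0.314, "DISI": 0.440, "LAAO": 0.145,
        "CTL": 0.086, "CRISP": 0.183, "SVMPi": 18.879,
    },
    "erythromelas": {
        "D49-PLA2": 1.893, "PI-SVMP": 0.526, "PIII-SVMP": 0.462,
        "SVSP": 0.214, "DISI": 0.453, "LAAO": 0.086, "CTL": 0.286,
        "CRISP": 0.017, "SVMPi": 14.626,
    },
    "pubescens": {
        "K49-PLA2": 2.329, "D49-PLA2": 0.164, "PI-SVMP": 0.530,
        "PIII-SVMP": 0.194, "SVSP": 0.482, "DISI": 0.627, "LAAO": 0.070,
        "CRISP": 0.217, "SVMPi": 13.861,
    },
    "pauloensis": {
        "K49-PLA2": 1.407, "D49-PLA2": 1.136, "PI-SVMP": 0.552,
        "PIII-SVMP": 0.179, "SVSP": 0.546, "DISI": 0.320, "LAAO": 0.095,
        "CRISP": 0.004, "SVMPi": 17.484,
    },
    "marmoratus": {
        "K49-PLA2": 0.764, "D49-PLA2": 0.657, "PI-SVMP": 0.787,
        "PIII-SVMP": 0.425, "SVSP": 0.575, "DISI": 0.373, "LAAO": 0.068,
        "CRISP": 0.122, "SVMPi": 18.564,
    },
}

# Antivenomics summary: maximal binding capacity of the pentabothropic
# F(ab')2 antivenom (SAB), mg venom bound / g antivenom.  Only four venoms
# were assayed in this study.
MAX_BIND_MG_PER_G: dict[str, float] = {
    "mattogrossensis": 93.08,
    "pubescens": 75.87,
    "neuwiedi": 165.67,
    "marmoratus": 102.9,
}

# Median effective dose of the antivenom against a 5xLD50 challenge,
# mg venom / g antivenom, with 95% CI.
ED50_MG_PER_G: dict[str, tuple[float, float, float]] = {
    # species: (estimate, ci_low, ci_high)
    "mattogrossensis": (143.4, 115.7, 188.6),
    "pauloensis": (135.9, 111.3, 174.8),
    "pubescens": (129.5, 86.9, 180.9),
    "diporus": (281.4, 228.8, 365.2),
    "neuwiedi": (210.4, 171.4, 272.4),
    "marmoratus": (154.5, 114.6, 237.0),
    "erythromelas": (161.8, 111.4, 295.8),
}

# Published neutralization potency, mg venom / g antivenom, with 95% CI.
POTENCY_PUBLISHED: dict[str, tuple[float, float, float]] = {
    "mattogrossensis": (114.7, 92.5, 150.9),
    "pauloensis": (108.8, 89.0, 139.9),
    "pubescens": (103.6, 69.5, 144.7),
    "diporus": (225.1, 183.1, 292.1),
    "neuwiedi": (168.3, 137.1, 217.9),
    "marmoratus": (123.6, 91.7, 189.6),
    "erythromelas": (129.4, 89.1, 236.7),
}

# Average venom yield per bite/milking, mg.
VENOM_YIELD_MG: dict[str, float] = {
    "mattogrossensis": 88.5,
    "pauloensis": 90.5,
    "pubescens": 36.5,
    "diporus": 134.0,
    "neuwiedi": 61.3,
    "marmoratus": 43.8,
    "erythromelas": 36.3,
}

# Antivenom constants.
N_CHALLENGE_LD50 = 5            # LD50 multiples in the neutralization challenge
FAB2_G_PER_VIAL = 0.4645        # g F(ab')2 per 10 mL antivenom vial
FAB2_G_PER_L = 46.45            # F(ab')2 concentration of the liquid antivenom
ANTIVENOM_MG_ON_COLUMN = 7.0    # mg F(ab')2 per immunoaffinity column
EXTINCTION_280_FAB2 = 1.36      # epsilon(0.1%), (mg/mL)^-1 cm^-1
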