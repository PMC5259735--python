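"""Published parameter estimates used as default simulation truth.

The original raw measurements were never deposited, so the package ships
the published best-model (maternal seed-size grouping) curve estimates for
each trajectory trait, plus the seed descriptor means, and uses them as the
generating truth for synthetic data.  Traits and their curve families:

=======  =============================  ===========  =====
trait    meaning                        family       units
=======  =============================  ===========  =====
TRL      total root length              expolinear   cm
FORK     number of root branches        expolinear   count
PRL      primary (tap) root length      gompertz     cm
AvBRL    average basal root length      gompertz     cm
LAREA    total leaf area                gompertz     cm^2
CDW      cotyledon dry weight (decay)   decay        g
SDLDW    seedling dry weight            gompertz     g
=======  =============================  ===========  =====

Trajectory traits (TRL..LAREA) were measured non-destructively on the same
plants every other day up to day 12; dry weights (CDW, SDLDW) come from
destructive harvests (one plant, one measurement).
"""

from __future__ import annotations

from types import MappingProxyType

from .curves import DecayParams, ExpolinearParams, GompertzParams

__all__ = [
    "TRAIT_FAMILY",
    "DESTRUCTIVE_TRAITS",
    "GROWTH_TRUTH",
    "SEED_TRAIT_TABLE",
    "SEED_WEIGHT_BY_CLASS",
    "SEED_TRAIT_N",
    "MEASUREMENT_DAYS",
]

MEASUREMENT_DAYS = (2, 4, 6, 8, 10, 12)

TRAIT_FAMILY = MappingProxyType({
    "TRL": "expolinear",
    "FORK": "expolinear",
    "PRL": "gompertz",
    "AvBRL": "gompertz",
    "LAREA": "gompertz",
    "SDLDW": "gompertz",
    "CDW": "decay",
})

DESTRUCTIVE_TRAITS = frozenset({"CDW", "SDLDW"})

# Best-model estimates under the maternal seed-size grouping ("large" =
# landrace maternal parent and its F1, "small" = wild maternal parent and
# its F1).
GROWTH_TRUTH = MappingProxyType({
    "TRL": MappingProxyType({
        "large": ExpolinearParams(cm=149.52, rm=0.92, tb=6.22),
        "small": ExpolinearParams(cm=84.86, rm=0.65, tb=6.14),
    }),
    "FORK": MappingProxyType({
        "large": ExpolinearParams(cm=317.59, rm=1.25, tb=6.72),
        "small": ExpolinearParams(cm=131.78, rm=0.74, tb=6.37),
    }),
    "PRL": MappingProxyType({
        "large": GompertzParams(wf=26.99, k=0.26, tt=5.51),
        "small": GompertzParams(wf=19.64, k=0.29, tt=3.18),
    }),
    "AvBRL": MappingProxyType({
        "large": GompertzParams(wf=12.93, k=0.33, tt=5.84),
        "small": GompertzParams(wf=6.09, k=0.37, tt=4.90),
    }),
    "LAREA": MappingProxyType({
        "large": GompertzParams(wf=46.9, k=0.64, tt=8.33),
        "small": GompertzParams(wf=28.39, k=0.62, tt=8.06),
    }),
    "CDW": MappingProxyType({
        "large": DecayParams(maximum=0.436, minimum=0.058, tt=6.012),
        "small": DecayParams(maximum=0.121, minimum=0.011, tt=2.727),
    }),
    "SDLDW": MappingProxyType({
        "large": GompertzParams(wf=0.55, k=0.26, tt=7.28),
        "small": GompertzParams(wf=0.19, k=0.24, tt=7.35),
    }),
})

SEED_TRAIT_N = 30  # seeds measured per line

# Seed descriptor means with one pooled standard error per column,
# by line: weight (g), length (mm), width (mm), height (mm), area (cm^2),
# perimeter (cm), circularity (-), aspect ratio (-).
_SEED_SE = MappingProxyType({
    "weight": 0.01, "length": 0.08, "width": 0.06, "height": 0.15,
    "area": 0.02, "perimeter": 0.09, "circularity": 0.02,
    "aspect_ratio": 0.02,
})

_SEED_MEANS = {
    "G19833": {"weight": 0.55, "length": 7.71, "width": 5.88,
               "height": 15.6, "area": 1.20, "perimeter": 4.90,
               "circularity": 0.64, "aspect_ratio": 1.89},
    "G19833xG23419": {"weight": 0.52, "length": 7.63, "width": 5.87,
                      "height": 15.2, "area": 1.19, "perimeter": 4.86,
                      "circularity": 0.61, "aspect_ratio": 1.90},
    "G23419xG19833": {"weight": 0.101, "length": 5.37, "width": 2.94,
                      "height": 7.8, "area": 0.39, "perimeter": 2.54,
                      "circularity": 0.77, "aspect_ratio": 1.48},
    "G23419": {"weight": 0.10, "length": 5.28, "width": 2.98,
               "height": 7.7, "area": 0.40, "perimeter": 2.56,
               "circularity": 0.76, "aspect_ratio": 1.48},
}

SEED_TRAIT_TABLE = MappingProxyType({
    line: MappingProxyType({
        trait: (mean, _SEED_SE[trait]) for trait, mean in traits.items()
    })
    for line, traits in _SEED_MEANS.items()
})

# Representative single-seed weights per maternal class, used for the
# per-gram allocation statistics.
SEED_WEIGHT_BY_CLASS = MappingProxyType({"large": 0.55, "small": 0.10})
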