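"""Printed inputs from the motivating California highway bat survey.

The package's defaults emulate a published acoustic survey of bat activity
along three San Francisco Bay highways: ten 300 m transects at three sites,
detectors at 0/100/300 m from the road edge, 174 detector-nights over two
seasons.  The fitted NB1 mixed-model coefficient tables from that study are
bundled here because they serve two roles: as the ground truth the synthetic
survey generator inverts, and as worked-example inputs for activity
prediction.
"""

from __future__ import annotations

import pandas as pd

from .design import DESIGN_COLUMNS

__all__ = [
    "REFERENCE_LIBRARY_SIZES",
    "SPECIES_CODES",
    "default_species_mix",
    "highway_study_betas",
]

#: Four-letter codes of the 15 species in the regional classifier library,
#: ordered by observed abundance in the survey.
SPECIES_CODES: tuple[str, ...] = (
    "TABR",  # Tadarida brasiliensis, Brazilian free-tailed bat
    "EPFU",  # Eptesicus fuscus, big brown bat
    "LANO",  # Lasionycteris noctivagans, silver-haired bat
    "LACI",  # Lasiurus cinereus, hoary bat
    "MYYU",  # Myotis yumanensis
    "MYLU",  # Myotis lucifugus
    "LABL",  # Lasiurus blossevillii
    "EUPE",  # Eumops perotis
    "ANPA",  # Antrozous pallidus
    "PAHE",  # Parastrellus hesperus
    "MYVO",  # Myotis volans
    "MYCA",  # Myotis californicus
    "COTO",  # Corynorhinus townsendii
    "MYEV",  # Myotis evotis
    "MYTH",  # Myotis thysanodes
)

#: Reference-library sizes (calls per species) of the survey's classifier
#: training library; totals 4437.
REFERENCE_LIBRARY_SIZES: dict[str, int] = {
    "TABR": 304,
    "EPFU": 884,
    "LANO": 365,
    "LACI": 174,
    "MYYU": 650,
    "MYLU": 219,
    "LABL": 98,
    "EUPE": 204,
    "ANPA": 353,
    "PAHE": 267,
    "MYVO": 198,
    "MYCA": 220,
    "COTO": 148,
    "MYEV": 169,
    "MYTH": 184,
}

# NB1 GLMM fixed-effect estimates (units: ln passes) for total activity and
# the four common species, in the canonical design-column order.
_BETAS = {
    "all": [3.4870, -0.3560, -0.6853, 0.0529, -0.0429, 0.0499,
            -0.3937, -1.0882, 0.5899, 0.3101, -0.3017, 1.0328,
            0.1384, 0.2129],
    "TABR": [2.6711, -0.2624, -0.6459, 0.0428, -0.0460, 0.0316,
             -0.4017, -0.8379, 0.8801, 0.4048, -0.4784, 0.5164,
             0.4238, 0.0849],
    "EPFU": [0.2755, -0.4410, -0.5909, 0.0874, 0.0735, 0.1177,
             -0.0068, -3.5913, 0.1765, 0.0225, 0.3632, 2.1542,
             -0.8726, 0.2592],
    "LANO": [-0.0029, -0.5513, -1.0851, 0.0510, 0.0119, 0.1558,
             -1.1843, -2.0287, 0.5549, 0.2496, -0.1876, 1.3285,
             -0.6150, 0.4402],
    "LACI": [1.0646, -0.3051, -0.5279, 0.0482, -0.0509, 0.0289,
             -0.1025, 0.1845, 0.6708, 0.0976, -0.6392, 0.4569,
             0.4750, 0.2159],
}

#: Observed composition of identified passes: the four common species made
#: up 40/25/15/7 percent of all passes; the remaining 13 percent is spread
#: evenly over the other library species.
COMMON_SPECIES_SHARES: dict[str, float] = {
    "TABR": 0.40,
    "EPFU": 0.25,
    "LANO": 0.15,
    "LACI": 0.07,
}


def highway_study_betas() -> pd.DataFrame:
    """Fixed-effect coefficient table of the highway study's NB1 GLMMs.

    Rows follow :data:`batpass.design.DESIGN_COLUMNS`; columns are the
    response: total activity (``all``) and the four common species.
    """
    return pd.DataFrame(_BETAS, index=list(DESIGN_COLUMNS), dtype=float)


def default_species_mix(species_codes) -> dict[str, float]:
    """Per-species activity weights mirroring the observed composition.

    The first four codes receive the common-species shares (40/25/15/7%);
    the remainder is spread evenly over the rest.  Weights sum to 1.
    """
    codes = list(species_codes)
    if len(codes) < 1:
        raise ValueError("need at least one species code")
    shares = list(COMMON_SPECIES_SHARES.values())
    mix: dict[str, float] = {}
    head = codes[: len(shares)]
    for code, share in zip(head, shares):
        mix[code] = share
    rest = codes[len(shares):]
    remainder = 1.0 - sum(mix.values())
    if rest:
        for code in rest:
            mix[code] = remainder / len(rest)
    else:
        # few species: renormalize the assigned shares
        total = sum(mix.values())
        mix = {c: v / total for c, v in mix.items()}
    assert abs(sum(mix.values()) - 1.0) < 1e-12
    return mix
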