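"""Reference parameter set from the turmeric / anti-ulcer interaction study.

Median-effect parameters (Dm in mg/kg, shape m) for the four single
treatments evaluated on the ethanol-induced gastric ulcer model in rats,
and for their equipotent 1:1 combinations, as reported by the original
study.  These printed values are the inputs for the worked examples, the
qualitative-reproduction simulations, and the acceptance checks; they are
never fitted here.

``INVERTED_ORDER_DM`` holds the experimental combination Dm observed when
the administration sequence was inverted (antiulcer drug given 15 min
before the turmeric extract or curcumin), which abolished the antagonism.
"""

from __future__ import annotations

from .combination import theoretical_dm
from .median_effect import MedianEffectModel

__all__ = [
    "SINGLE_DRUG_PARAMS",
    "COMBINATION_PARAMS",
    "INVERTED_ORDER_DM",
    "single_drug_fit",
    "combination_fit",
    "reference_interaction_ci",
]

#: drug -> (Dm mg/kg, m)
SINGLE_DRUG_PARAMS: dict[str, tuple[float, float]] = {
    "TAE": (0.004, 0.21),
    "curcumin": (0.99, 0.38),
    "ranitidine": (17.40, 0.62),
    "bismuth_subsalicylate": (11.50, 1.49),
}

#: (drug1, drug2) -> (experimental combination Dm mg/kg, combination m)
COMBINATION_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("TAE", "ranitidine"): (31.11, 1.19),
    ("curcumin", "ranitidine"): (31.79, 0.74),
    ("TAE", "bismuth_subsalicylate"): (6.35, 0.98),
    ("curcumin", "bismuth_subsalicylate"): (8.02, 1.16),
}

#: inverted administration order -> experimental combination Dm (mg/kg)
INVERTED_ORDER_DM: dict[tuple[str, str], float] = {
    ("ranitidine", "TAE"): 7.49,
    ("ranitidine", "curcumin"): 7.66,
}


def single_drug_fit(drug: str) -> MedianEffectModel:
    """Fitted median-effect model carrying a reference drug's (Dm, m)."""
    dm, m = SINGLE_DRUG_PARAMS[drug]
    return MedianEffectModel.from_params(dm, m)


def combination_fit(drug1: str, drug2: str) -> MedianEffectModel:
    """Fitted model carrying a reference combination's (Dm Exp, m)."""
    dm, m = COMBINATION_PARAMS[(drug1, drug2)]
    return MedianEffectModel.from_params(dm, m)


def reference_interaction_ci(drug1: str, drug2: str) -> float:
    """CI at fa = 0.5 implied by the reference table: Dm Exp / Dm Theo.

    For inverted-order pairs the experimental Dm comes from
    ``INVERTED_ORDER_DM`` and the single-drug parameters from the same
    two drugs.
    """
    if (drug1, drug2) in COMBINATION_PARAMS:
        dm_exp = COMBINATION_PARAMS[(drug1, drug2)][0]
    elif (drug1, drug2) in INVERTED_ORDER_DM:
        dm_exp = INVERTED_ORDER_DM[(drug1, drug2)]
    else:
        raise KeyError(f"unknown combination {(drug1, drug2)!r}")
    dm_a = SINGLE_DRUG_PARAMS[drug1][0]
    dm_b = SINGLE_DRUG_PARAMS[drug2][0]
    return dm_exp / theoretical_dm(dm_a, dm_b)
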