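"""Fixed-length molecular representations (structure-only and electronic)."""

from tmcbench.representations.base import (
    Featurizer,
    FeaturizerParams,
    LayoutError,
    RepresentationVector,
    UnsupportedVariantError,
    featurize_all,
    get_state,
)
from tmcbench.representations.slatm import SLATMFeaturizer
from tmcbench.representations.soap import SOAPFeaturizer, radial_basis_matrix, real_sph_harm
from tmcbench.representations.spahm import DensityFeaturizer, EigenFeaturizer

REGISTRY = {
    "slatm": SLATMFeaturizer,
    "soap": SOAPFeaturizer,
    "eigen": EigenFeaturizer,
    "density": DensityFeaturizer,
}


def fit_featurizer(rep_name: str, structures, params: FeaturizerParams | None = None):
    """Fit a featurizer by name, freezing element set, bag layout and padding."""
    try:
        cls = REGISTRY[rep_name]
    except KeyError:
        raise ValueError(f"unknown representation {rep_name!r}; choose from {sorted(REGISTRY)}") from None
    return cls(structures, params or FeaturizerParams())


__all__ = [
    "Featurizer",
    "FeaturizerParams",
    "LayoutError",
    "RepresentationVector",
    "UnsupportedVariantError",
    "featurize_all",
    "fit_featurizer",
    "get_state",
    "REGISTRY",
    "SLATMFeaturizer",
    "SOAPFeaturizer",
    "EigenFeaturizer",
    "DensityFeaturizer",
    "real_sph_harm",
    "radial_basis_matrix",
]
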