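"""Feature assembly: one named vector per tumour.

Feature families follow the pipeline's 201-feature inventory:

====================  =====  ==========================================
group                 count  content
====================  =====  ==========================================
attenuation               1  whole-tumour attenuation coefficient
mean_qus                 10  mean of each QUS map, core and margin
core_margin              10  core/margin ratio + contrast ratio per map
texture                  20  4 GLCM features x 5 core parametric maps
texture_derivative      160  16 derivatives x 5 maps x {core, margin}
====================  =====  ==========================================

The exact family decomposition summing to 201 is not uniquely determined by
the headline total; the default registry above (first-pass texture from the
core only, derivatives from core and margin) is the documented-group
decomposition that reproduces it, and a both-region registry (221 features)
is available.  Molecular subtype is carried alongside the numeric features
and one-hot encoded by the classifier, not counted in the registry total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .maps import QUS_PARAMETERS, ParametricMap
from .texture import (
    TEXTURE_FEATURE_NAMES,
    GLCMConfig,
    region_texture,
    texture_derivative,
    texture_map,
)

__all__ = [
    "MolecularSubtype",
    "FeatureVector",
    "molecular_subtype",
    "region_mean",
    "core_margin_features",
    "default_registry",
    "both_region_registry",
    "assemble_features",
]

FEATURE_GROUPS = (
    "attenuation",
    "mean_qus",
    "core_margin",
    "texture",
    "texture_derivative",
    "molecular",
)


class MolecularSubtype(str, Enum):
    """Receptor-status subtype of a breast tumour."""

    ERBB2 = "ERBB2+"
    TRIPLE_NEGATIVE = "TripleNegative"
    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"


def molecular_subtype(er: str, pr: str, her2: str) -> MolecularSubtype:
    """Subtype from ER/PR/HER2 status flags ('+' or '-').

    ERBB2+ is ER-/PR-/HER2+; triple negative is ER-/PR-/HER2-; Luminal-A is
    ER+ and/or PR+ with HER2-; Luminal-B is ER+ and/or PR+ with HER2+.
    """
    flags = {}
    for name, value in (("er", er), ("pr", pr), ("her2", her2)):
        if value not in ("+", "-"):
            raise ValueError(f"{name} status must be '+' or '-', got {value!r}")
        flags[name] = value == "+"
    if flags["er"] or flags["pr"]:
        return MolecularSubtype.LUMINAL_B if flags["her2"] else MolecularSubtype.LUMINAL_A
    return MolecularSubtype.ERBB2 if flags["her2"] else MolecularSubtype.TRIPLE_NEGATIVE


def region_mean(pmap: ParametricMap) -> float:
    """Arithmetic mean of a map over its valid pixels."""
    if not pmap.validity_mask.any():
        raise ValueError("parametric map has no valid pixels")
    return float(pmap.valid_values.mean())


def core_margin_features(core_mean: float, margin_mean: float) -> dict[str, float]:
    """Core-to-margin ratio and Michelson-style contrast ratio.

    ratio = core/margin; contrast = |core − margin| / (|core| + |margin|).
    A zero denominator flags the feature missing (NaN) rather than raising.
    """
    ratio = core_mean / margin_mean if margin_mean != 0 else np.nan
    denom = abs(core_mean) + abs(margin_mean)
    contrast = abs(core_mean - margin_mean) / denom if denom != 0 else np.nan
    return {"ratio": ratio, "contrast_ratio": contrast}


def default_registry() -> list[tuple[str, str]]:
    """201-feature registry: core-only first-pass texture, both-region
    derivatives."""
    return _build_registry(texture_regions=("core",), derivative_regions=("core", "margin"))


def both_region_registry() -> list[tuple[str, str]]:
    """221-feature registry with first-pass texture from both regions."""
    return _build_registry(
        texture_regions=("core", "margin"), derivative_regions=("core", "margin")
    )


def _build_registry(
    texture_regions: tuple[str, ...], derivative_regions: tuple[str, ...]
) -> list[tuple[str, str]]:
    registry: list[tuple[str, str]] = [("ATT", "attenuation")]
    for region in ("core", "margin"):
        for param in QUS_PARAMETERS:
            registry.append((f"{region}-{param}-mean", "mean_qus"))
    for param in QUS_PARAMETERS:
        registry.append((f"{param}-CMR", "core_margin"))
        registry.append((f"{param}-CMCR", "core_margin"))
    for region in texture_regions:
        for param in QUS_PARAMETERS:
            for feat in TEXTURE_FEATURE_NAMES:
                registry.append((f"{region}-{param}-{feat}", "texture"))
    for region in derivative_regions:
        for param in QUS_PARAMETERS:
            for first in TEXTURE_FEATURE_NAMES:
                for second in TEXTURE_FEATURE_NAMES:
                    registry.append(
                        (f"{region}-{param}-{first}-{second}", "texture_derivative")
                    )
    names = [n for n, _ in registry]
    assert len(names) == len(set(names)), "registry names must be unique"
    return registry


@dataclass
class FeatureVector:
    """Ordered named features plus group labels for one tumour."""

    tumour_id: str
    names: list[str]
    values: np.ndarray
    groups: dict[str, str]
    subtype: MolecularSubtype | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        missing = [n for n in self.names if n not in self.groups]
        if missing:
            raise ValueError(f"features without a group label: {missing[:5]}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.tumour_id)

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))


def assemble_features(
    core_maps: dict[str, ParametricMap],
    margin_maps: dict[str, ParametricMap],
    attenuation: float,
    subtype: MolecularSubtype | None = None,
    registry: list[tuple[str, str]] | None = None,
    glcm_config: GLCMConfig | None = None,
    texture_window: int = 5,
    texture_step: int = 1,
    tumour_id: str = "tumour",
) -> FeatureVector:
    """Aggregate parametric maps into the registry's feature families.

    A feature whose maps cannot support it (empty region, zero denominator,
    no valid texture window) is flagged missing (NaN), never dropped, so the
    vector length is a pure function of the registry.
    """
    if registry is None:
        registry = default_registry()
    if glcm_config is None:
        glcm_config = GLCMConfig()
    maps = {"core": core_maps, "margin": margin_maps}

    computed: dict[str, float] = {"ATT": float(attenuation)}
    means: dict[tuple[str, str], float] = {}
    for region, rmaps in maps.items():
        for param in QUS_PARAMETERS:
            try:
                means[(region, param)] = region_mean(rmaps[param])
            except (KeyError, ValueError):
                means[(region, param)] = np.nan
            computed[f"{region}-{param}-mean"] = means[(region, param)]
    for param in QUS_PARAMETERS:
        cm = core_margin_features(means[("core", param)], means[("margin", param)])
        computed[f"{param}-CMR"] = cm["ratio"]
        computed[f"{param}-CMCR"] = cm["contrast_ratio"]

    wanted = {name for name, _ in registry}
    for region, rmaps in maps.items():
        for param in QUS_PARAMETERS:
            tex_names = [f"{region}-{param}-{f}" for f in TEXTURE_FEATURE_NAMES]
            deriv_prefix = f"{region}-{param}-"
            need_texture = any(n in wanted for n in tex_names)
            need_deriv = any(
                f"{deriv_prefix}{a}-{b}" in wanted
                for a in TEXTURE_FEATURE_NAMES
                for b in TEXTURE_FEATURE_NAMES
            )
            if not (need_texture or need_deriv):
                continue
            pmap = rmaps.get(param)
            if need_texture:
                try:
                    feats = region_texture(pmap, glcm_config)
                    for fname, value in feats.as_dict().items():
                        computed[f"{region}-{param}-{fname}"] = value
                except (ValueError, AttributeError):
                    for fname in TEXTURE_FEATURE_NAMES:
                        computed[f"{region}-{param}-{fname}"] = np.nan
            if need_deriv:
                try:
                    tmaps = texture_map(pmap, glcm_config, texture_window, texture_step)
                    deriv = texture_derivative(tmaps, glcm_config)
                    for key, value in deriv.items():
                        computed[f"{region}-{key}"] = value
                except (ValueError, AttributeError):
                    for a in TEXTURE_FEATURE_NAMES:
                        for b in TEXTURE_FEATURE_NAMES:
                            computed[f"{region}-{param}-{a}-{b}"] = np.nan

    names = [name for name, _ in registry]
    values = np.array([computed.get(name, np.nan) for name in names])
    groups = dict(registry)
    if subtype is not None:
        groups["subtype"] = "molecular"
    return FeatureVector(
        tumour_id=tumour_id, names=names, values=values, groups=groups, subtype=subtype
    )
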