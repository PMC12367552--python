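"""Infrastructure layer construction.

Per-type count rasters are first normalized to [0, 1] by their own maximum
(count distributions are wildly skewed across types — power poles vastly
outnumber, say, water towers — so cross-type comparability requires it),
then aggregated into the economic / social / environmental categories by
equal weighting.  The environmental composite additionally folds in green
space, air quality and heat duration:

    Env = 0.5 * CI_env + 0.5 * exp(Green) / (Air + Heat)

where the denominator is the simplified form of ln(e^Air * e^Heat) and is
floored at a small epsilon because the normalized layers can both be exactly
zero.  The socio-economic layers are calibrated against night-time lights
(NTL) with a log-log regression,

    ln(NTL) = a * ln(I') + b,

fit over cells where both sides are positive, and applied as
I = exp(b) * I'**a (with I = 0 kept at I' = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from infraccess.grid import GridLayer

__all__ = [
    "DEFAULT_TYPE_CATALOG",
    "CATEGORIES",
    "sensitivity_catalog",
    "EnvInputs",
    "CalibrationFit",
    "normalize_type_layer",
    "aggregate_category",
    "environmental_composite",
    "fit_calibration",
    "apply_calibration",
]

CATEGORIES = ("economic", "social", "environmental")

#: Default mapping from infrastructure type to category: business-supporting
#: systems are economic, service systems social, living-condition systems
#: environmental.
DEFAULT_TYPE_CATALOG: dict[str, str] = {
    "telecom": "economic",
    "energy": "economic",
    "transport": "economic",
    "health": "social",
    "education": "social",
    "water": "environmental",
    "waste": "environmental",
}


def sensitivity_catalog() -> dict[str, str]:
    """Type catalog for the sensitivity reclassification.

    Water and waste systems are moved out of the environmental category into
    the socio-economic ones (water with economic utilities, waste with social
    services), leaving the environmental layer to green space, air and heat
    alone.
    """
    catalog = dict(DEFAULT_TYPE_CATALOG)
    catalog["water"] = "economic"
    catalog["waste"] = "social"
    return catalog


def validate_catalog(catalog: dict[str, str]) -> None:
    for t, c in catalog.items():
        if c not in CATEGORIES:
            raise ValueError(f"type {t!r} mapped to unknown category {c!r}")


@dataclass
class EnvInputs:
    """Aligned [0, 1] inputs of the environmental composite."""

    ci_env: GridLayer
    green: GridLayer
    air: GridLayer
    heat: GridLayer

    def validate(self) -> None:
        for name in ("green", "air", "heat", "ci_env"):
            layer: GridLayer = getattr(self, name)
            self.ci_env.require_same_grid(layer, name)
            vals = layer.valid_values()
            if vals.size and (vals.min() < 0 or vals.max() > 1 + 1e-12):
                raise ValueError(f"{name} layer has values outside [0, 1]")


@dataclass
class CalibrationFit:
    """Coefficients of the log-log NTL calibration ln(NTL) = a ln(I') + b."""

    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration fit needs at least 3 cells")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


def normalize_type_layer(layer: GridLayer) -> GridLayer:
    """Scale a non-negative count layer by its maximum valid value.

    The output lies in [0, 1] with at least one cell equal to 1.  Raises on
    all-masked or all-zero layers (no meaningful maximum).
    """
    vals = layer.valid_values()
    if vals.size == 0:
        raise ValueError("cannot normalize an all-masked layer")
    if np.any(vals < 0):
        raise ValueError("count layer has negative values")
    peak = vals.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero layer")
    return layer.copy_with(layer.values / peak)


def aggregate_category(layers: list[GridLayer]) -> GridLayer:
    """Cell-wise equal-weight mean of aligned layers.

    A cell is averaged over the layers valid there; it is masked only when
    every input is masked.
    """
    if not layers:
        raise ValueError("no layers to aggregate")
    base = layers[0]
    for layer in layers[1:]:
        base.require_same_grid(layer)
    sums = np.zeros(base.shape)
    counts = np.zeros(base.shape, dtype=int)
    for layer in layers:
        sums += np.where(layer.mask, layer.values, 0.0)
        counts += layer.mask
    mask = counts > 0
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=mask)
    return base.copy_with(means, mask)


def environmental_composite(env: EnvInputs, epsilon: float = 1e-6) -> GridLayer:
    """Environmental infrastructure composite.

    Computes ``0.5 * CI_env + 0.5 * exp(Green) / max(Air + Heat, epsilon)``
    — the denominator is ln(e^Air * e^Heat) = Air + Heat, floored at
    ``epsilon`` so the cells where both normalized exposure layers are zero
    stay finite.  Output is masked wherever any input is masked.
    """
    env.validate()
    ci, g, a, h = env.ci_env, env.green, env.air, env.heat
    mask = ci.mask & g.mask & a.mask & h.mask
    denom = np.maximum(a.values + h.values, epsilon)
    with np.errstate(over="ignore"):
        second = np.exp(g.values) / denom
    out = 0.5 * ci.values + 0.5 * second
    out = np.where(mask, out, np.nan)
    return ci.copy_with(out, mask)


def fit_calibration(
    infra: GridLayer,
    ntl: GridLayer,
    mask: np.ndarray | None = None,
) -> CalibrationFit:
    """OLS fit of ln(NTL) on ln(I') over jointly valid, strictly positive cells.

    ``mask`` restricts the fit to a study region (e.g. an urban-plus-buffer
    footprint); cells with zero infrastructure or zero lights are always
    excluded because their logarithm is undefined.
    """
    infra.require_same_grid(ntl, "ntl")
    sel = infra.mask & ntl.mask & (infra.values > 0) & (ntl.values > 0)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    x = np.log(infra.values[sel])
    y = np.log(ntl.values[sel])
    if x.size < 3:
        raise ValueError(f"calibration needs >= 3 usable cells, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln(infrastructure); fit undefined")
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        n=int(x.size),
    )


def apply_calibration(infra_prime: GridLayer, fit: CalibrationFit) -> GridLayer:
    """Apply ln(I) = a ln(I') + b, i.e. I = exp(b) * I'**a, keeping I = 0 at I' = 0.

    For a > 0 the transform is strictly increasing, so cell rankings are
    preserved.
    """
    vals = infra_prime.values
    if np.any(vals[infra_prime.mask] < 0):
        raise ValueError("calibration input must be non-negative")
    out = np.zeros_like(vals)
    pos = infra_prime.mask & (vals > 0)
    out[pos] = np.exp(fit.intercept) * vals[pos] ** fit.slope
    out = np.where(infra_prime.mask, out, np.nan)
    return infra_prime.copy_with(out)
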