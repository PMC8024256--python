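"""CRM equation forms, prediction with additivity, and store partitioning.

Two mean functions relate a component ratio R_c to a predictor X:

* nonlinear:  R_c = exp(beta0 + beta1 / X)
* linear:     R_c = beta0 + beta1 * X

with X one of dbh (cm), dbh^2 (cm^2, a basal-area proxy) or dbh^2 * ht
(cm^2 m, a stem-volume proxy).  Stem, branch and twig ratios are modeled;
the foliage ratio is one minus their sum, which makes any prediction — and
any biomass or CO2 store partitioned with it — exactly additive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from . import reference
from .records import COMPONENTS, SYSTEM_COMPONENTS, RatioRecord, TreeRecord


class Predictor(str, Enum):
    """Tree attribute used as the CRM predictor."""

    DBH = "dbh"
    DBH_SQ = "dbh2"
    DBH_SQ_HT = "dbh2ht"


class ModelForm(str, Enum):
    """Mean-function family of the ratio equations."""

    NONLINEAR = "nonlinear"
    LINEAR = "linear"


@dataclass(frozen=True)
class EquationParams:
    """Coefficients (beta0, beta1) of one component-ratio equation."""

    component: str
    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            raise ValueError("equation parameters must be finite")


@dataclass(frozen=True)
class PartitionResult:
    """A total store split additively into the four component stores."""

    total: float
    amounts: dict[str, float]
    ratios: RatioRecord

    def __post_init__(self) -> None:
        s = sum(self.amounts.values())
        if self.total > 0 and abs(s - self.total) > 1e-9 * self.total:
            raise ValueError("component amounts do not sum to the total")


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the dbh range the model was fitted on."""


def transform_predictor(tree: TreeRecord, spec: Predictor) -> float:
    """Compute the predictor value X for one tree.

    Units: cm for dbh, cm^2 for dbh^2, cm^2*m for dbh^2*ht (no rescaling).
    """
    spec = Predictor(spec)
    if spec is Predictor.DBH:
        return tree.dbh
    if spec is Predictor.DBH_SQ:
        return tree.dbh**2
    if tree.ht is None:
        raise ValueError(
            f"tree {tree.tree_id!r} has no height; predictor {spec.value!r} "
            "requires ht"
        )
    return tree.dbh**2 * tree.ht


def eval_ratio(form: ModelForm, params: EquationParams, x: float) -> float:
    """Evaluate one ratio equation at predictor value ``x`` (no clamping)."""
    form = ModelForm(form)
    if form is ModelForm.NONLINEAR:
        if x == 0:
            raise ValueError("nonlinear form is undefined at X = 0")
        return math.exp(params.beta0 + params.beta1 / x)
    return params.beta0 + params.beta1 * x


def _as_param_map(
    params: Mapping[str, EquationParams] | Sequence[EquationParams],
) -> dict[str, EquationParams]:
    if isinstance(params, Mapping):
        out = dict(params)
    else:
        out = {p.component: p for p in params}
    missing = [c for c in SYSTEM_COMPONENTS if c not in out]
    if missing:
        raise ValueError(f"missing equation parameters for {missing}")
    return out


def params_from_pairs(pairs: Mapping[str, tuple[float, float]]) -> dict[str, EquationParams]:
    """Build an EquationParams map from ``{component: (beta0, beta1)}``."""
    return {c: EquationParams(c, *pairs[c]) for c in SYSTEM_COMPONENTS}


def predict_system(
    params: Mapping[str, EquationParams] | Sequence[EquationParams],
    form: ModelForm,
    spec: Predictor,
    tree: TreeRecord,
    *,
    clamp: bool = True,
    training_range: tuple[float, float] = reference.TRAINING_DBH_RANGE,
) -> RatioRecord:
    """Predict the four component ratios for one tree.

    Stem, branch and twig come from their equations; foliage is the
    complement ``1 - (R_stem + R_branch + R_twig)`` so the four ratios sum
    to one exactly.  With ``clamp=True`` (default) each modeled ratio is
    clamped to [0, 1], a negative foliage complement is floored at zero,
    and the four values are renormalized to sum to one; the returned record
    is flagged ``clamped`` whenever this altered any value.  With
    ``clamp=False`` raw values pass through (they may leave [0, 1]).

    A warning is emitted when the tree's dbh lies outside the dbh range the
    coefficients were fitted on.
    """
    pmap = _as_param_map(params)
    lo, hi = training_range
    if not (lo <= tree.dbh <= hi):
        warnings.warn(
            f"dbh {tree.dbh:g} cm outside fitted range [{lo:g}, {hi:g}] cm; "
            "prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    x = transform_predictor(tree, spec)
    raw = [eval_ratio(form, pmap[c], x) for c in SYSTEM_COMPONENTS]
    foliage = 1.0 - sum(raw)
    if not clamp:
        return RatioRecord(*raw, foliage, clamped=False)

    clipped = [min(max(r, 0.0), 1.0) for r in raw]
    altered = clipped != raw
    fol = 1.0 - sum(clipped)
    if fol < 0.0:
        fol = 0.0
        altered = True
    values = clipped + [fol]
    total = sum(values)
    if total != 1.0:  # only reachable after clamping; pure float no-op otherwise
        values = [v / total for v in values]
    return RatioRecord(*values, clamped=altered)


def partition_total(total: float, ratios: RatioRecord) -> PartitionResult:
    """Split a stand or tree total into component stores via the ratios.

    ``total`` may be in any mass or CO2 unit; each component receives
    ``total * R_c``, so the parts sum back to the total.
    """
    if total < 0:
        raise ValueError(f"total must be non-negative, got {total!r}")
    amounts = {c: total * ratios.component(c) for c in COMPONENTS}
    return PartitionResult(total=total, amounts=amounts, ratios=ratios)


def hybrid_estimate(
    volume_m3: float,
    bef_mg_m3: float,
    params: Mapping[str, EquationParams] | Sequence[EquationParams],
    form: ModelForm,
    spec: Predictor,
    tree: TreeRecord,
    **predict_kwargs,
) -> PartitionResult:
    """Volume-to-biomass hybrid estimate partitioned into components (kg).

    Total dry biomass is ``volume * BEF`` (Mg, converted to kg), then split
    into the four component stores with the ratios predicted for ``tree``.
    """
    if volume_m3 < 0:
        raise ValueError("volume must be non-negative")
    if bef_mg_m3 <= 0:
        raise ValueError("biomass expansion factor must be positive")
    total_kg = volume_m3 * bef_mg_m3 * 1000.0
    ratios = predict_system(params, form, spec, tree, **predict_kwargs)
    return partition_total(total_kg, ratios)
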