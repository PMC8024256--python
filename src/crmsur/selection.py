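"""Fitting and ranking the six model-by-predictor CRM candidates.

The candidate grid crosses the two mean-function families (linear,
nonlinear) with the three predictors (dbh, dbh^2, dbh^2*ht).  Candidates
are ranked by the count of equations whose slope differs significantly
from zero (more first), then mean per-equation residual standard error
(smaller first), then overall system R2 — the significance-before-RSE
priority mirrors how the final model was chosen, with the residual-plot
criterion operationalized as exported residual tables plus a
within-decile dispersion statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .model import ModelForm, Predictor
from .records import SYSTEM_COMPONENTS
from .sur import SystemData, SystemFit, fit_lsur, fit_nsur, significance_stars

#: Canonical candidate order: forms major, predictors minor.
CANDIDATE_ORDER = tuple(
    (form, spec)
    for form, spec in product(
        (ModelForm.NONLINEAR, ModelForm.LINEAR),
        (Predictor.DBH, Predictor.DBH_SQ, Predictor.DBH_SQ_HT),
    )
)


@dataclass
class Candidate:
    """One model-by-predictor combination with its fit or failure record."""

    form: ModelForm
    spec: Predictor
    fit: SystemFit | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.fit is not None

    @property
    def label(self) -> str:
        return f"{ModelForm(self.form).value}-{Predictor(self.spec).value}"


def fit_all_candidates(ratios: pd.DataFrame, **fit_options) -> list[Candidate]:
    """Fit every candidate; failures are recorded, never dropped.

    A missing or incomplete ``ht_m`` column marks the two dbh^2*ht
    candidates infeasible while the four dbh-only candidates proceed.
    """
    grid: list[Candidate] = []
    for form, spec in CANDIDATE_ORDER:
        try:
            data = SystemData.from_ratios(ratios, spec)
            if form is ModelForm.LINEAR:
                fit = fit_lsur(data, spec, **fit_options)
            else:
                fit = fit_nsur(data, spec, **fit_options)
            grid.append(Candidate(form, spec, fit=fit))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            grid.append(Candidate(form, spec, error=str(exc)))
    return grid


def _rank_key(cand: Candidate):
    if not cand.ok:
        return (2, 0, np.inf, 0.0, cand.label)
    fit = cand.fit
    n_sig = sum(1 for f in fit.fits.values() if f.p_beta1 <= 0.05)
    mean_rse = float(np.mean([f.rse for f in fit.fits.values()]))
    return (
        0 if fit.converged else 1,
        -n_sig,
        mean_rse,
        -fit.overall_r2,
        cand.label,
    )


def rank_models(grid: list[Candidate]) -> pd.DataFrame:
    """Rank candidates and return the machine-readable selection table.

    Deterministic: the ranking depends only on each candidate's own fit
    (with the label as final tie-break), never on grid order.
    """
    if not any(c.ok for c in grid):
        raise ValueError("no successful fit in the candidate grid")
    ordered = sorted(grid, key=_rank_key)
    rows = []
    for rank, cand in enumerate(ordered, start=1):
        row = {
            "rank": rank,
            "form": ModelForm(cand.form).value,
            "predictor": Predictor(cand.spec).value,
            "converged": bool(cand.fit.converged) if cand.ok else False,
            "error": cand.error or "",
        }
        for c in SYSTEM_COMPONENTS:
            if cand.ok:
                f = cand.fit.fits[c]
                row[f"rse_{c}"] = f.rse
                row[f"stars_{c}"] = significance_stars(f.p_beta1)
            else:
                row[f"rse_{c}"] = np.nan
                row[f"stars_{c}"] = ""
        row["n_significant"] = (
            sum(1 for f in cand.fit.fits.values() if f.p_beta1 <= 0.05)
            if cand.ok
            else 0
        )
        row["overall_r2"] = cand.fit.overall_r2 if cand.ok else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def residual_table(fit: SystemFit) -> pd.DataFrame:
    """Long per-tree residual table: one row per tree per component.

    ``residual = observed - predicted``; suitable for residual-vs-predicted
    plots or export.
    """
    rows = []
    n = fit.n
    ids = fit.tree_ids if fit.tree_ids is not None else [str(i) for i in range(n)]
    for c in SYSTEM_COMPONENTS:
        f = fit.fits[c]
        for i in range(n):
            rows.append(
                {
                    "tree_id": ids[i],
                    "component": c,
                    "predicted": float(f.fitted[i]),
                    "residual": float(f.residuals[i]),
                    "observed": float(f.fitted[i] + f.residuals[i]),
                }
            )
    return pd.DataFrame(rows)


def residual_dispersion(fit: SystemFit, n_bins: int = 10) -> pd.DataFrame:
    """SD of residuals within quantile bins of the predicted values.

    A numeric stand-in for the visual residual-plot criterion: clustered
    predictions show up as bins with few distinct predicted values and
    inflated within-bin residual spread.
    """
    table = residual_table(fit)
    out = []
    for c, sub in table.groupby("component"):
        q = min(n_bins, max(1, sub["predicted"].nunique()))
        bins = pd.qcut(sub["predicted"].rank(method="first"), q, labels=False)
        sd = sub.groupby(bins)["residual"].std(ddof=1)
        out.append(
            {
                "component": c,
                "n_bins": int(q),
                "mean_within_bin_sd": float(sd.mean()),
                "max_within_bin_sd": float(sd.max()),
            }
        )
    return pd.DataFrame(out)
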