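"""Reference constants for the 9-year-old *Zelkova serrata* plantation study.

This module collects the published study-site structure (diameter-class
census, destructive-sampling allocation, class-mean dbh/ht with their
coefficients of variation), the mean observed component ratios, the stand
CO2 stock used for the worked partition, and the final fitted linear-SUR
coefficient set, which ships as a packaged JSON file and serves both as the
default prediction model and as the calibration truth of the synthetic-data
generator.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .records import SYSTEM_COMPONENTS

#: Diameter-class labels in increasing dbh order.
CLASS_LABELS = ("<=5", "5-10", "10-15", "15-20", ">20")

#: Class boundaries (cm).  The census recorded classes of 5-cm width; the
#: smallest census tree is taken at 2 cm and the open-ended top class is
#: truncated at 25 cm (both configurable in the generator).
CLASS_EDGES = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0)

#: Number of census trees per diameter class (total 921).
CENSUS_COUNTS = (167, 518, 208, 25, 3)

#: Destructive-sample allocation per class (total 12; none from the top
#: class, which held only three trees).
SAMPLE_ALLOCATION = (2, 4, 3, 3, 0)

#: Mean dbh (cm) of the sampled trees per class (top class not sampled).
CLASS_MEAN_DBH = (4.43, 8.28, 13.37, 18.63)

#: Mean height (m) of the sampled trees per class.
CLASS_MEAN_HT = (5.85, 6.61, 9.46, 9.23)

#: Coefficient of variation of sampled-tree height per class, as fractions.
#: The unsampled top class reuses the adjacent class value.
CLASS_HT_CV = (0.189, 0.159, 0.151, 0.260, 0.260)

#: dbh range (cm) spanned by the destructively sampled trees; predictions
#: outside this range trigger an extrapolation warning.
TRAINING_DBH_RANGE = (3.9, 19.7)

#: Mean observed component ratios (stem, branch, twig, foliage).
MEAN_RATIOS = {"stem": 0.463, "branch": 0.399, "twig": 0.092, "foliage": 0.046}

#: Standard deviations of the observed component ratios.
SD_RATIOS = {"stem": 0.118, "branch": 0.136, "twig": 0.033, "foliage": 0.023}

#: Stand-level CO2 stock (t CO2 / ha) of an average plantation of this
#: species, used in the worked partition example.
STAND_CO2_STOCK = 452.2

#: Published biomass expansion factors (Mg dry biomass per m3 stem volume)
#: for 25- and 46-year-old plantations of this species.
BIOMASS_EXPANSION_FACTORS = {"age_25": 1.328, "age_46": 1.528}


def load_reference_fit() -> dict:
    """Load the packaged final linear-SUR coefficient set.

    Returns the parsed JSON object: per-component coefficient entries
    (``beta0``, ``beta1``, standard errors, p-values, ``rse``, ``r2``),
    the cross-equation residual correlation matrix, the overall system R2,
    and the model form and predictor it belongs to.
    """
    text = resources.files("crmsur").joinpath("data/reference_fit.json").read_text()
    return json.loads(text)


def reference_params() -> dict[str, tuple[float, float]]:
    """Per-component ``(beta0, beta1)`` of the reference linear-dbh fit."""
    fit = load_reference_fit()
    return {
        c: (fit["equations"][c]["beta0"], fit["equations"][c]["beta1"])
        for c in SYSTEM_COMPONENTS
    }


def reference_error_correlation() -> np.ndarray:
    """3x3 cross-equation residual correlation (stem, branch, twig order)."""
    fit = load_reference_fit()
    return np.asarray(fit["correlation"], dtype=float)


def reference_error_sd() -> tuple[float, ...]:
    """Per-equation residual standard errors of the reference fit."""
    fit = load_reference_fit()
    return tuple(fit["equations"][c]["rse"] for c in SYSTEM_COMPONENTS)


def fit_height_curve(
    dbh: tuple[float, ...] = CLASS_MEAN_DBH,
    ht: tuple[float, ...] = CLASS_MEAN_HT,
) -> tuple[float, float]:
    """Fit a power mean-height curve ht = c * dbh**d through class means.

    A log-log least-squares line through the (mean dbh, mean ht) pairs of
    the sampled diameter classes; used as the generator's height model.
    """
    x = np.log(np.asarray(dbh, dtype=float))
    y = np.log(np.asarray(ht, dtype=float))
    d, logc = np.polyfit(x, y, 1)
    return float(np.exp(logc)), float(d)
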