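"""Field-weight conversion and component-ratio computation.

Destructively sampled trees are weighed fresh in the field per component;
a subsample of each component is oven-dried, and its dry:fresh ratio
converts the whole-component fresh weight to dry biomass.  Component
ratios R_c = B_c / AGB are then the responses of the CRM equations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import COMPONENTS, BiomassRecord, FieldSample, RatioRecord, TreeRecord


def moisture_ratio(sample_fresh: float, sample_dry: float) -> float:
    """Dry-to-fresh weight ratio of one component subsample.

    Raises on non-positive fresh weight, non-positive dry weight, or a dry
    weight exceeding the fresh weight.
    """
    if sample_fresh <= 0:
        raise ValueError(f"sample fresh weight must be positive, got {sample_fresh!r}")
    if sample_dry <= 0:
        raise ValueError(f"sample dry weight must be positive, got {sample_dry!r}")
    if sample_dry > sample_fresh:
        raise ValueError(
            f"sample dry weight {sample_dry!r} exceeds fresh weight {sample_fresh!r}"
        )
    return sample_dry / sample_fresh


def to_dry_biomass(fresh_field: float, ratio: float) -> float:
    """Convert a field fresh weight (kg) to dry biomass via a moisture ratio."""
    if fresh_field < 0:
        raise ValueError(f"fresh field weight must be non-negative, got {fresh_field!r}")
    if not 0 < ratio <= 1:
        raise ValueError(f"moisture ratio must lie in (0, 1], got {ratio!r}")
    return fresh_field * ratio


def pooled_moisture_ratios(samples: Iterable[FieldSample]) -> dict[str, float]:
    """Moisture ratios pooled across trees: total dry over total fresh per component."""
    fresh = dict.fromkeys(COMPONENTS, 0.0)
    dry = dict.fromkeys(COMPONENTS, 0.0)
    for s in samples:
        for c in COMPONENTS:
            fresh[c] += s.sample_fresh.get(c, 0.0)
            dry[c] += s.sample_dry.get(c, 0.0)
    return {c: moisture_ratio(fresh[c], dry[c]) for c in COMPONENTS}


def biomass_from_field(
    sample: FieldSample, pooled: dict[str, float] | None = None
) -> BiomassRecord:
    """Dry biomass of the four components of one tree from field weights.

    By default each component uses the tree's own subsample moisture ratio;
    passing ``pooled`` (e.g. from :func:`pooled_moisture_ratios`) applies
    ratios shared across trees instead.  A component with zero field fresh
    weight yields zero dry biomass without requiring a subsample.
    """
    out = {}
    for c in COMPONENTS:
        ff = sample.fresh_field.get(c, 0.0)
        if ff == 0.0:
            out[c] = 0.0
            continue
        if pooled is not None:
            r = pooled[c]
        else:
            r = moisture_ratio(sample.sample_fresh[c], sample.sample_dry[c])
        out[c] = to_dry_biomass(ff, r)
    return BiomassRecord(out["stem"], out["branch"], out["twig"], out["foliage"])


def compute_ratios(rec: BiomassRecord) -> RatioRecord:
    """Component ratios R_c = B_c / AGB of one tree.

    Scale-invariant in the biomasses; zero-biomass components give ratio 0.
    Raises when AGB is zero.
    """
    agb = rec.agb
    if agb <= 0:
        raise ValueError("cannot compute ratios for a tree with zero AGB")
    return RatioRecord(*(rec.component(c) / agb for c in COMPONENTS))


def ratios_frame(
    trees: Sequence[TreeRecord], biomass: Sequence[BiomassRecord]
) -> pd.DataFrame:
    """Per-tree ratio table with columns tree_id, dbh_cm, ht_m, r_*."""
    if len(trees) != len(biomass):
        raise ValueError("trees and biomass records differ in length")
    rows = []
    for t, b in zip(trees, biomass):
        r = compute_ratios(b)
        rows.append(
            {
                "tree_id": t.tree_id,
                "dbh_cm": t.dbh,
                "ht_m": np.nan if t.ht is None else t.ht,
                **{f"r_{c}": r.component(c) for c in COMPONENTS},
            }
        )
    return pd.DataFrame(rows)


def ratio_summary(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, min and max of each component ratio across trees."""
    cols = [f"r_{c}" for c in COMPONENTS]
    missing = [c for c in cols if c not in ratios.columns]
    if missing:
        raise ValueError(f"ratio table missing columns {missing}")
    out = pd.DataFrame(
        {
            "component": COMPONENTS,
            "mean": [ratios[c].mean() for c in cols],
            "sd": [ratios[c].std(ddof=1) for c in cols],
            "min": [ratios[c].min() for c in cols],
            "max": [ratios[c].max() for c in cols],
        }
    )
    return out


def prepare_ratios(biomass_table: pd.DataFrame, use_field_weights: bool = False,
                   pool_moisture: bool = False) -> pd.DataFrame:
    """Build the per-tree ratio table from a biomass table.

    The table must carry ``tree_id, dbh_cm, ht_m`` and, by default, the dry
    biomass columns ``b_<component>_kg``.  With ``use_field_weights=True``
    dry biomass is instead reconstructed from the fresh field weights
    ``fw_<component>_kg`` and the subsample pairs ``sf_/sd_<component>_kg``
    (optionally pooling moisture ratios across trees).
    """
    trees = [
        TreeRecord(
            str(row.tree_id),
            float(row.dbh_cm),
            None if pd.isna(row.ht_m) else float(row.ht_m),
        )
        for row in biomass_table.itertuples()
    ]
    if use_field_weights:
        samples = []
        for row in biomass_table.itertuples():
            samples.append(
                FieldSample(
                    fresh_field={c: getattr(row, f"fw_{c}_kg") for c in COMPONENTS},
                    sample_fresh={c: getattr(row, f"sf_{c}_kg") for c in COMPONENTS},
                    sample_dry={c: getattr(row, f"sd_{c}_kg") for c in COMPONENTS},
                )
            )
        pooled = pooled_moisture_ratios(samples) if pool_moisture else None
        biomass = [biomass_from_field(s, pooled) for s in samples]
    else:
        biomass = [
            BiomassRecord(*(getattr(row, f"b_{c}_kg") for c in COMPONENTS))
            for row in biomass_table.itertuples()
        ]
    return ratios_frame(trees, biomass)
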