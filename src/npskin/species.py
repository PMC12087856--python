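"""Cross-species skin similarity for choosing animal penetration models.

Species are compared in one body region (default: back) on their SC,
epidermis and dermis thicknesses.  Each layer is z-scored across the
compared species before computing pairwise Euclidean distances —
without standardization the millimetre-scale dermis would swamp the
micrometre-scale SC.  Signed percent differences vs human are reported
alongside for each layer and for hair-follicle diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from npskin.datamodel import DatasetError, SkinReferenceTable

_LAYERS = ["sc_thickness", "epidermis_thickness", "dermis_thickness"]


def percent_difference(reference: float, other: float) -> float:
    """Signed percent difference of ``other`` relative to ``reference``."""
    if reference == 0:
        raise DatasetError("zero reference value")
    return 100.0 * (other - reference) / reference


@dataclass
class SimilarityReport:
    percent_diff: pd.DataFrame  # species x (sc/epidermis/dermis/hf_diameter)
    distance: pd.DataFrame  # symmetric species x species
    ranking: list[str]  # non-human species ordered by distance to human
    region: str


def species_similarity(
    table: SkinReferenceTable, region: str = "back", standardize: bool = True
) -> SimilarityReport:
    """Pairwise skin-thickness similarity across species in one region."""
    species = [sp for sp in table.species() if region in table.regions(sp)]
    rows, kept = [], []
    for sp in species:
        d = table.lookup(sp, region)
        vec = [d.sc_thickness, d.epidermis_thickness, d.dermis_thickness]
        if any(v is None or not np.isfinite(v) for v in vec):
            warnings.warn(f"{sp} dropped: missing layer values in {region}")
            continue
        rows.append(vec + [d.hf_diameter])
        kept.append(sp)
    if len(kept) < 2:
        raise DatasetError(f"fewer than 2 species with region {region!r}")

    M = np.asarray(rows, float)
    thick = M[:, :3]
    if standardize:
        mu = thick.mean(axis=0)
        sd = thick.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        thick = (thick - mu) / sd
    D = squareform(pdist(thick))
    distance = pd.DataFrame(D, index=kept, columns=kept)

    pct = pd.DataFrame(index=kept, columns=_LAYERS + ["hf_diameter"], dtype=float)
    if "human" in kept:
        h = table.lookup("human", region)
        refs = [h.sc_thickness, h.epidermis_thickness, h.dermis_thickness,
                h.hf_diameter]
        for sp, row in zip(kept, rows):
            pct.loc[sp] = [percent_difference(r, v) for r, v in zip(refs, row)]
        ranking = (
            distance.loc["human"].drop("human").sort_values().index.tolist()
        )
    else:
        ranking = []
    return SimilarityReport(
        percent_diff=pct, distance=distance, ranking=ranking, region=region
    )
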