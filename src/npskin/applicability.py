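"""Applicability domain and in-silico NP populations.

The applicability domain is the convex hull of the training data after
PCA to a few components (default 3): a prediction is considered
in-domain when the projected point falls inside the hull.  Large
in-silico populations are drawn uniformly between the minimum and
maximum of every NP descriptor observed in the source dataset (on the
log scale for log-transformed descriptors), with the skin and
experimental context fixed to a human reference, and the per-layer
descriptor ranges of the predicted population are compared by
Kruskal-Wallis with Dunn's post hoc test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from sklearn.decomposition import PCA

from npskin.datamodel import (
    CSV_COLUMNS,
    DEPTH_CLASSES,
    DatasetError,
    ExperimentCondition,
    SkinDescriptor,
    records_to_frame,
)
from npskin.stats import dunn_test, kruskal_wallis


@dataclass
class ApplicabilityDomain:
    pca: PCA
    hull: ConvexHull
    delaunay: Delaunay
    training_scores: np.ndarray
    d: int

    def contains(self, X: np.ndarray) -> np.ndarray:
        """Hull membership (boundary included) of encoded rows."""
        scores = self.pca.transform(np.asarray(X, float))[:, : self.d]
        return self.delaunay.find_simplex(scores) >= 0


def fit_applicability_domain(X_train: np.ndarray, d: int = 3) -> ApplicabilityDomain:
    """PCA to ``d`` components, then the convex hull of the scores."""
    X = np.asarray(X_train, float)
    if np.isnan(X).any():
        raise DatasetError("applicability domain requires a complete matrix")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < d:
        warnings.warn(f"rank-deficient training matrix: reducing d from {d} to {rank}")
        d = max(int(rank), 1)
    if X.shape[0] <= d + 1:
        raise DatasetError(f"need more than {d + 1} training points")
    pca = PCA(n_components=d).fit(X)
    scores = pca.transform(X)
    hull = ConvexHull(scores)
    tri = Delaunay(scores)
    return ApplicabilityDomain(
        pca=pca, hull=hull, delaunay=tri, training_scores=scores, d=d
    )


def contains(ad: ApplicabilityDomain, x: np.ndarray) -> np.ndarray:
    return ad.contains(np.atleast_2d(x))


# ---------------------------------------------------------------------------
# in-silico population
# ---------------------------------------------------------------------------

#: human-context defaults for the 100k experiment
DEFAULT_CONDITION = ExperimentCondition(temperature=32.0, contact_time=24.0,
                                        in_vivo=False)

#: NP descriptor columns sampled between dataset bounds (log-uniform
#: where the model uses log scale)
_SAMPLED_LOG = ["core_diameter_nm", "concentration_ug_ml"]


@dataclass
class InSilicoPopulation:
    """Uniformly sampled NP table in a fixed human skin context."""

    frame: pd.DataFrame
    bounds: dict[str, tuple[float, float]]
    skin_context: SkinDescriptor
    condition: ExperimentCondition
    seed: int
    in_domain: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.frame)


def generate_insilico(
    dataset,
    n: int = 100_000,
    skin: SkinDescriptor | None = None,
    condition: ExperimentCondition = DEFAULT_CONDITION,
    seed: int = 0,
    medium_levels: tuple[str, ...] | None = None,
) -> InSilicoPopulation:
    """Draw ``n`` random NPs between the source dataset's descriptor bounds.

    Numeric NP descriptors are sampled uniformly between the observed
    minimum and maximum (log-uniform for diameter and concentration);
    categorical descriptors uniformly over the observed levels; geometry
    descriptors are re-derived from diameter and shape so the sampled
    particles remain physically consistent.  Skin and condition columns
    are fixed to the given human context.
    """
    source = dataset if isinstance(dataset, pd.DataFrame) else records_to_frame(dataset)
    if skin is None:
        from npskin.synth import builtin_skin_reference
        skin = builtin_skin_reference().lookup("human", "back")
    rng = np.random.default_rng(seed)

    bounds = {}
    for col in ["core_diameter_nm", "concentration_ug_ml", "hydrophobicity_value"]:
        vals = pd.to_numeric(source[col], errors="coerce").dropna()
        if not len(vals) or not np.isfinite([vals.min(), vals.max()]).all():
            raise DatasetError(f"unbounded descriptor: {col}")
        bounds[col] = (float(vals.min()), float(vals.max()))

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    lo, hi = bounds["core_diameter_nm"]
    diameter = log_uniform(lo, hi, n)
    lo, hi = bounds["concentration_ug_ml"]
    concentration = log_uniform(lo, hi, n)

    def observed_levels(col):
        levels = sorted(source[col].dropna().unique())
        if not levels:
            raise DatasetError(f"no observed levels for {col}")
        return levels

    shape = rng.choice(observed_levels("shape"), size=n)
    if medium_levels is None:
        medium_levels = tuple(observed_levels("medium"))
    medium = rng.choice(list(medium_levels), size=n)
    np_class = rng.choice(observed_levels("np_class"), size=n)

    # hydrophobicity per scale, within the observed per-scale range
    hydro_scale = np.where(np_class == "inorganic", "contact_angle_deg", "logKow")
    hydro = np.empty(n)
    for scale in ("logKow", "contact_angle_deg"):
        sel = hydro_scale == scale
        vals = pd.to_numeric(
            source.loc[source["hydrophobicity_scale"] == scale,
                       "hydrophobicity_value"], errors="coerce").dropna()
        if len(vals):
            hydro[sel] = rng.uniform(vals.min(), vals.max(), size=int(sel.sum()))
        else:
            hydro[sel] = np.nan

    rods = source.loc[source["shape"] == "rod", "rod_length_nm"].dropna()
    aspect = (
        (rods / source.loc[rods.index, "core_diameter_nm"]).clip(1.1, 50.0)
        if len(rods) else pd.Series([5.0])
    )
    rod_length = np.where(
        shape == "rod",
        diameter * rng.uniform(aspect.min(), aspect.max(), size=n),
        np.nan,
    )
    # vectorized geometry (sphere fallback for 'other', cylinder for rods)
    sa = np.pi * diameter**2
    vol = np.pi * diameter**3 / 6.0
    rod = shape == "rod"
    if rod.any():
        r = diameter[rod] / 2.0
        sa[rod] = 2.0 * np.pi * r * r + 2.0 * np.pi * r * rod_length[rod]
        vol[rod] = np.pi * r * r * rod_length[rod]
    sv = sa / vol

    frame = pd.DataFrame({
        "source_id": [f"insilico-{i:06d}" for i in range(n)],
        "depth": "Surface",  # placeholder until predicted
        "core_diameter_nm": diameter,
        "shape": shape,
        "rod_length_nm": rod_length,
        "surface_area_nm2": sa,
        "volume_nm3": vol,
        "sv_ratio_per_nm": sv,
        "concentration_ug_ml": concentration,
        "medium": medium,
        "np_class": np_class,
        "hydrophobicity_value": hydro,
        "hydrophobicity_scale": hydro_scale,
        "species": skin.species,
        "region": skin.region,
        "sc_thickness_um": skin.sc_thickness,
        "epidermis_thickness_um": skin.epidermis_thickness,
        "dermis_thickness_um": skin.dermis_thickness,
        "hf_density_per_cm2": skin.hf_density,
        "hf_diameter_um": skin.hf_diameter,
        "lipid_lipophilicity": skin.lipid_lipophilicity,
        "lipid_polarity": skin.lipid_polarity,
        "temperature_c": condition.temperature,
        "contact_time_h": condition.contact_time,
        "in_vivo": condition.in_vivo,
    }, columns=CSV_COLUMNS)
    return InSilicoPopulation(
        frame=frame, bounds=bounds, skin_context=skin,
        condition=condition, seed=seed,
    )


# ---------------------------------------------------------------------------
# per-layer descriptor ranges
# ---------------------------------------------------------------------------

#: descriptors compared across predicted layers
RANGE_DESCRIPTORS = [
    "core_diameter_nm",
    "surface_area_nm2",
    "volume_nm3",
    "sv_ratio_per_nm",
    "concentration_ug_ml",
    "hydrophobicity_value",
]


@dataclass
class LayerRangeReport:
    kruskal: pd.DataFrame  # descriptor, H, p, significant
    dunn: pd.DataFrame  # descriptor, layer pair, z, p_raw, p_adjusted
    ranges: pd.DataFrame  # descriptor x layer: min / median / max
    predicted: np.ndarray = field(repr=False, default=None)


def layer_ranges(
    population: InSilicoPopulation,
    model,
    encoder,
    adjust: str = "holm",
    alpha: float = 0.05,
    descriptors=RANGE_DESCRIPTORS,
) -> LayerRangeReport:
    """Which descriptors differ between predicted penetration layers."""
    fm = encoder.transform(population.frame)
    X = np.nan_to_num(fm.values, nan=0.0)  # missing hydro scale never sampled
    pred = model.predict(X)
    present = [c for c in DEPTH_CLASSES if np.sum(pred == c) >= 2]
    skipped = [c for c in DEPTH_CLASSES if 0 < np.sum(pred == c) < 2]
    if skipped:
        warnings.warn(f"layers with < 2 members excluded: {skipped}")
    if len(present) < 2:
        raise DatasetError("model predicts fewer than 2 layers on the population")

    kw_rows, dunn_frames, range_rows = [], [], []
    for col in descriptors:
        vals = pd.to_numeric(population.frame[col], errors="coerce").to_numpy()
        groups = [vals[(pred == c) & ~np.isnan(vals)] for c in present]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        h, p = kruskal_wallis(groups)
        kw_rows.append({
            "descriptor": col, "H": h, "p": p,
            "significant": p < alpha,
        })
        dt = dunn_test(groups, labels=present, p_adjust=adjust)
        dt.insert(0, "descriptor", col)
        dunn_frames.append(dt)
        for c in present:
            g = vals[(pred == c) & ~np.isnan(vals)]
            range_rows.append({
                "descriptor": col, "layer": c,
                "min": float(np.min(g)), "median": float(np.median(g)),
                "max": float(np.max(g)), "n": int(len(g)),
            })
    return LayerRangeReport(
        kruskal=pd.DataFrame(kw_rows),
        dunn=pd.concat(dunn_frames, ignore_index=True) if dunn_frames
        else pd.DataFrame(),
        ranges=pd.DataFrame(range_rows),
        predicted=pred,
    )
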