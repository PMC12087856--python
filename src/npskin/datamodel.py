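"""Domain types, derived descriptors, and CSV I/O for penetration records.

A penetration record couples a nanoparticle description, a skin
description, and the experimental conditions with the observed
penetration depth, one of five ordered classes::

    Surface < SC < Epidermis < Dermis < Distant

Numeric NP size descriptors (diameter, surface area, volume,
concentration) span several orders of magnitude and are log10-transformed
before modelling; all numeric columns are z-standardized with parameters
fitted on the modelling set only, so hold-out data and in-silico
populations are projected through the same transform without leakage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEPTH_CLASSES: tuple[str, ...] = ("Surface", "SC", "Epidermis", "Dermis", "Distant")

SHAPES = ("sphere", "rod", "other")
MEDIA = ("aqueous", "oil", "emulsion", "other")
NP_CLASSES = ("inorganic", "polymeric", "other")
HYDRO_SCALES = ("logKow", "contact_angle_deg")
SPECIES = ("human", "pig", "rat", "mouse", "rabbit")
REGIONS = ("face", "abdomen", "arm", "back", "breast", "ear", "other")

#: fields that may legitimately be absent from a literature record
MISSABLE_FIELDS = (
    "hydrophobicity_value",
    "concentration",
    "temperature",
    "contact_time",
)


class DatasetError(ValueError):
    """Raised for malformed records or dataset files."""


def _check_enum(value: str, levels: Sequence[str], name: str) -> str:
    if value not in levels:
        raise DatasetError(f"{name}={value!r} is not one of {list(levels)}")
    return value


def _check_positive(value, name: str):
    if value is not None and not value > 0:
        raise DatasetError(f"{name} must be > 0, got {value}")
    return value


def derive_geometry(
    diameter: float, shape: str, rod_length: float | None = None
) -> tuple[float, float, float]:
    """Surface area (nm^2), volume (nm^3) and surface-to-volume ratio (1/nm).

    Spheres use ``pi d^2``, ``pi d^3 / 6`` and ``6/d``; rods are treated
    as closed cylinders of diameter ``diameter`` and length
    ``rod_length``.  Unreported / irregular shapes fall back to the
    sphere formulas with a warning, the common assumption when a source
    does not state the shape.
    """
    _check_positive(diameter, "diameter")
    _check_enum(shape, SHAPES, "shape")
    if shape == "rod":
        if rod_length is None:
            raise DatasetError("rod_length is required for shape='rod'")
        _check_positive(rod_length, "rod_length")
        r = diameter / 2.0
        surface = 2.0 * math.pi * r * r + 2.0 * math.pi * r * rod_length
        volume = math.pi * r * r * rod_length
    else:
        if shape == "other":
            warnings.warn(
                "shape='other' has no closed-form geometry; assuming a sphere",
                stacklevel=2,
            )
        surface = math.pi * diameter * diameter
        volume = math.pi * diameter**3 / 6.0
    return surface, volume, surface / volume


def weighted_lipid_properties(
    lipids: Sequence[tuple[float, float, float]]
) -> tuple[float, float]:
    """Mass-weighted SC-lipid lipophilicity and polarity.

    ``lipids`` is a sequence of ``(mass_percent, lipophilicity,
    polarity)`` triples.  Mass percentages are renormalized if their sum
    lies within [95, 105] (rounding slack in published compositions),
    otherwise rejected.
    """
    if not lipids:
        raise DatasetError("empty lipid list")
    masses = np.asarray([l[0] for l in lipids], dtype=float)
    if np.any(masses < 0):
        raise DatasetError("negative lipid mass percentage")
    total = masses.sum()
    if not (95.0 <= total <= 105.0):
        raise DatasetError(
            f"lipid mass percentages sum to {total:.2f}, outside [95, 105]"
        )
    w = masses / total
    lipo = float(np.dot(w, [l[1] for l in lipids]))
    polar = float(np.dot(w, [l[2] for l in lipids]))
    return lipo, polar


@dataclass
class NanoparticleDescriptor:
    """Eight NP descriptors: size/shape geometry, concentration, medium,
    material class and outer-layer hydrophobicity.

    Hydrophobicity lives on two scales: logKow for organic-type particles
    (polymeric/other) and water contact angle (degrees) for inorganic
    ones; the encoder later folds both into one normalized column plus a
    scale indicator.
    """

    core_diameter: float  # nm
    shape: str = "sphere"
    rod_length: float | None = None  # nm, rods only
    surface_area: float | None = None  # nm^2
    volume: float | None = None  # nm^3
    sv_ratio: float | None = None  # 1/nm
    concentration: float | None = None  # ug/mL
    medium: str = "aqueous"
    np_class: str = "inorganic"
    hydrophobicity_value: float | None = None
    hydrophobicity_scale: str = "contact_angle_deg"

    def __post_init__(self):
        _check_positive(self.core_diameter, "core_diameter")
        _check_enum(self.shape, SHAPES, "shape")
        _check_enum(self.medium, MEDIA, "medium")
        _check_enum(self.np_class, NP_CLASSES, "np_class")
        _check_enum(self.hydrophobicity_scale, HYDRO_SCALES, "hydrophobicity_scale")
        _check_positive(self.concentration, "concentration")
        if self.shape == "rod" and self.rod_length is None:
            raise DatasetError("rod_length is required for shape='rod'")
        if self.surface_area is None or self.volume is None or self.sv_ratio is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sa, vol, sv = derive_geometry(
                    self.core_diameter, self.shape, self.rod_length
                )
            self.surface_area = sa if self.surface_area is None else self.surface_area
            self.volume = vol if self.volume is None else self.volume
            self.sv_ratio = sv if self.sv_ratio is None else self.sv_ratio
        if self.hydrophobicity_value is not None:
            expected = "contact_angle_deg" if self.np_class == "inorganic" else "logKow"
            if self.hydrophobicity_scale != expected:
                raise DatasetError(
                    f"np_class={self.np_class!r} requires hydrophobicity_scale="
                    f"{expected!r}, got {self.hydrophobicity_scale!r}"
                )


@dataclass
class SkinDescriptor:
    """Skin specimen: species, body region, layer thicknesses (um), hair
    follicle density (1/cm^2) and diameter (um), and mass-weighted SC
    lipid lipophilicity / polarity."""

    species: str
    region: str
    sc_thickness: float  # um
    epidermis_thickness: float  # um
    dermis_thickness: float  # um
    hf_density: float  # 1/cm^2
    hf_diameter: float  # um
    lipid_lipophilicity: float
    lipid_polarity: float

    def __post_init__(self):
        _check_enum(self.species, SPECIES, "species")
        _check_enum(self.region, REGIONS, "region")
        for name in ("sc_thickness", "epidermis_thickness", "dermis_thickness"):
            _check_positive(getattr(self, name), name)
        _check_positive(self.hf_density, "hf_density")
        if not (5.0 <= self.hf_diameter <= 500.0):
            raise DatasetError(
                f"hf_diameter={self.hf_diameter} um outside plausible band [5, 500]"
            )


@dataclass
class ExperimentCondition:
    """Temperature (C), NP-skin contact time (h), in vivo vs ex vivo."""

    temperature: float | None
    contact_time: float | None  # hours
    in_vivo: bool = False

    def __post_init__(self):
        if self.temperature is not None and not (15.0 <= self.temperature <= 45.0):
            raise DatasetError(
                f"temperature={self.temperature} C outside [15, 45]"
            )
        _check_positive(self.contact_time, "contact_time")


@dataclass
class PenetrationRecord:
    """One literature penetration experiment with its depth label."""

    np: NanoparticleDescriptor
    skin: SkinDescriptor
    cond: ExperimentCondition
    depth: str
    source_id: str = ""

    def __post_init__(self):
        _check_enum(self.depth, DEPTH_CLASSES, "depth")


@dataclass
class SkinReferenceTable:
    """Mean skin descriptors keyed by (species, region).

    ``n_sources`` records how many source values were averaged for each
    row; rows aggregate at least three where the literature allows.
    """

    rows: dict[tuple[str, str], SkinDescriptor]
    n_sources: dict[tuple[str, str], int] = field(default_factory=dict)

    def lookup(self, species: str, region: str) -> SkinDescriptor:
        key = (species, region)
        if key not in self.rows:
            raise KeyError(f"no skin reference for {key}")
        return self.rows[key]

    def species(self) -> list[str]:
        return sorted({s for s, _ in self.rows})

    def regions(self, species: str) -> list[str]:
        return sorted(r for s, r in self.rows if s == species)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (sp, rg), d in self.rows.items():
            row = asdict(d)
            row["n_sources"] = self.n_sources.get((sp, rg), 3)
            recs.append(row)
        return pd.DataFrame(recs).set_index(["species", "region"]).sort_index()


# ---------------------------------------------------------------------------
# flat-frame representation and CSV I/O
# ---------------------------------------------------------------------------

#: CSV column dictionary (order defines the file layout)
CSV_COLUMNS = [
    "source_id",
    "depth",
    "core_diameter_nm",
    "shape",
    "rod_length_nm",
    "surface_area_nm2",
    "volume_nm3",
    "sv_ratio_per_nm",
    "concentration_ug_ml",
    "medium",
    "np_class",
    "hydrophobicity_value",
    "hydrophobicity_scale",
    "species",
    "region",
    "sc_thickness_um",
    "epidermis_thickness_um",
    "dermis_thickness_um",
    "hf_density_per_cm2",
    "hf_diameter_um",
    "lipid_lipophilicity",
    "lipid_polarity",
    "temperature_c",
    "contact_time_h",
    "in_vivo",
]

_NUMERIC_CSV = {
    "core_diameter_nm",
    "rod_length_nm",
    "surface_area_nm2",
    "volume_nm3",
    "sv_ratio_per_nm",
    "concentration_ug_ml",
    "hydrophobicity_value",
    "sc_thickness_um",
    "epidermis_thickness_um",
    "dermis_thickness_um",
    "hf_density_per_cm2",
    "hf_diameter_um",
    "lipid_lipophilicity",
    "lipid_polarity",
    "temperature_c",
    "contact_time_h",
}


def record_to_row(rec: PenetrationRecord) -> dict:
    n, s, c = rec.np, rec.skin, rec.cond
    return {
        "source_id": rec.source_id,
        "depth": rec.depth,
        "core_diameter_nm": n.core_diameter,
        "shape": n.shape,
        "rod_length_nm": n.rod_length,
        "surface_area_nm2": n.surface_area,
        "volume_nm3": n.volume,
        "sv_ratio_per_nm": n.sv_ratio,
        "concentration_ug_ml": n.concentration,
        "medium": n.medium,
        "np_class": n.np_class,
        "hydrophobicity_value": n.hydrophobicity_value,
        "hydrophobicity_scale": n.hydrophobicity_scale,
        "species": s.species,
        "region": s.region,
        "sc_thickness_um": s.sc_thickness,
        "epidermis_thickness_um": s.epidermis_thickness,
        "dermis_thickness_um": s.dermis_thickness,
        "hf_density_per_cm2": s.hf_density,
        "hf_diameter_um": s.hf_diameter,
        "lipid_lipophilicity": s.lipid_lipophilicity,
        "lipid_polarity": s.lipid_polarity,
        "temperature_c": c.temperature,
        "contact_time_h": c.contact_time,
        "in_vivo": c.in_vivo,
    }


def row_to_record(row: dict) -> PenetrationRecord:
    def num(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    in_vivo = row["in_vivo"]
    if isinstance(in_vivo, str):
        low = in_vivo.strip().lower()
        if low not in ("true", "false", "1", "0"):
            raise DatasetError(f"in_vivo={in_vivo!r} is not a boolean")
        in_vivo = low in ("true", "1")
    npd = NanoparticleDescriptor(
        core_diameter=num("core_diameter_nm"),
        shape=str(row["shape"]),
        rod_length=num("rod_length_nm"),
        surface_area=num("surface_area_nm2"),
        volume=num("volume_nm3"),
        sv_ratio=num("sv_ratio_per_nm"),
        concentration=num("concentration_ug_ml"),
        medium=str(row["medium"]),
        np_class=str(row["np_class"]),
        hydrophobicity_value=num("hydrophobicity_value"),
        hydrophobicity_scale=str(row["hydrophobicity_scale"]),
    )
    skin = SkinDescriptor(
        species=str(row["species"]),
        region=str(row["region"]),
        sc_thickness=num("sc_thickness_um"),
        epidermis_thickness=num("epidermis_thickness_um"),
        dermis_thickness=num("dermis_thickness_um"),
        hf_density=num("hf_density_per_cm2"),
        hf_diameter=num("hf_diameter_um"),
        lipid_lipophilicity=num("lipid_lipophilicity"),
        lipid_polarity=num("lipid_polarity"),
    )
    cond = ExperimentCondition(
        temperature=num("temperature_c"),
        contact_time=num("contact_time_h"),
        in_vivo=bool(in_vivo),
    )
    return PenetrationRecord(
        np=npd, skin=skin, cond=cond,
        depth=str(row["depth"]), source_id=str(row.get("source_id", "")),
    )


def records_to_frame(records: Iterable[PenetrationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([record_to_row(r) for r in records], columns=CSV_COLUMNS)
    return df


def frame_to_records(frame: pd.DataFrame) -> list[PenetrationRecord]:
    records, errors = [], []
    for idx, row in frame.iterrows():
        try:
            records.append(row_to_record(row.to_dict()))
        except (DatasetError, KeyError, TypeError) as exc:  # collect, report all
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise DatasetError("unparseable rows:\n" + "\n".join(errors))
    return records


def write_dataset(records: Iterable[PenetrationRecord], path) -> None:
    """Write records as UTF-8 comma-separated CSV; empty cell = missing."""
    records_to_frame(records).to_csv(path, index=False)


def read_dataset(path) -> list[PenetrationRecord]:
    """Read a penetration dataset CSV, reporting bad rows by line number."""
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"missing mandatory columns: {missing_cols}")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

#: source-frame numeric columns that enter the model log10-transformed
LOG_COLUMNS = {
    "core_diameter_nm",
    "surface_area_nm2",
    "volume_nm3",
    "concentration_ug_ml",
}

#: numeric model columns: (feature name, source column)
NUMERIC_FEATURES = [
    ("log10_core_diameter", "core_diameter_nm"),
    ("log10_surface_area", "surface_area_nm2"),
    ("log10_volume", "volume_nm3"),
    ("sv_ratio", "sv_ratio_per_nm"),
    ("log10_concentration", "concentration_ug_ml"),
    ("temperature", "temperature_c"),
    ("contact_time", "contact_time_h"),
    ("sc_thickness", "sc_thickness_um"),
    ("epidermis_thickness", "epidermis_thickness_um"),
    ("dermis_thickness", "dermis_thickness_um"),
    ("hf_density", "hf_density_per_cm2"),
    ("hf_diameter", "hf_diameter_um"),
    ("lipid_lipophilicity", "lipid_lipophilicity"),
    ("lipid_polarity", "lipid_polarity"),
]

ONEHOT_GROUPS = [
    ("medium", "medium", MEDIA),
    ("species", "species", SPECIES),
    ("region", "region", REGIONS),
    ("shape", "shape", SHAPES),
    ("np_class", "np_class", NP_CLASSES),
]


@dataclass
class FeatureMatrix:
    """Encoded design matrix with missingness bookkeeping.

    ``values`` holds NaN exactly where ``missing_mask`` is True.
    ``encoding_map`` maps each one-hot group to its ``level -> column``
    mapping; ``transform_log`` records which source columns were
    log10-transformed and the fitted standardization parameters.
    """

    values: np.ndarray
    feature_names: list[str]
    missing_mask: np.ndarray
    encoding_map: dict[str, dict[str, int]]
    transform_log: dict
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        nan = np.isnan(self.values)
        if not np.array_equal(nan, self.missing_mask):
            raise DatasetError("NaN outside missing_mask (or mask without NaN)")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> int:
        return self.feature_names.index(name)

    def group_columns(self, group: str) -> list[int]:
        return sorted(self.encoding_map[group].values())

    def decode_categorical(self, group: str) -> list[str]:
        """Recover original categorical levels from a one-hot group."""
        inv = {col: lvl for lvl, col in self.encoding_map[group].items()}
        cols = self.group_columns(group)
        block = self.values[:, cols]
        out = []
        for row in block:
            j = int(np.argmax(row))
            out.append(inv[cols[j]])
        return out

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.copy(),
            feature_names=list(self.feature_names),
            missing_mask=self.missing_mask.copy(),
            encoding_map={g: dict(m) for g, m in self.encoding_map.items()},
            transform_log=dict(self.transform_log),
            ids=list(self.ids),
        )


class FeatureEncoder:
    """Fit-once / transform-many encoder from penetration records to a
    :class:`FeatureMatrix`.

    The transform applies, in order: log10 to the NP size and
    concentration columns, min-max normalization of hydrophobicity
    within each of its two scales, one-hot encoding of categoricals,
    and z-standardization of numeric columns using the moments fitted
    on the (modelling) data passed to :meth:`fit`.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize
        self.fitted_ = False

    def fit(self, data) -> "FeatureEncoder":
        frame = self._as_frame(data)
        if len(frame) == 0:
            raise DatasetError("cannot fit an encoder on an empty dataset")
        self.hydro_range_: dict[str, tuple[float, float]] = {}
        for scale in HYDRO_SCALES:
            vals = frame.loc[
                frame["hydrophobicity_scale"] == scale, "hydrophobicity_value"
            ].dropna()
            if len(vals):
                lo, hi = float(vals.min()), float(vals.max())
            else:
                lo, hi = 0.0, 1.0
            self.hydro_range_[scale] = (lo, hi if hi > lo else lo + 1.0)
        raw = self._raw_numeric(frame)
        self.means_ = raw.mean(axis=0, skipna=True).to_dict()
        stds = raw.std(axis=0, ddof=0, skipna=True)
        self.stds_ = {k: (v if v > 0 else 1.0) for k, v in stds.to_dict().items()}
        self.fitted_ = True
        return self

    @staticmethod
    def _as_frame(data) -> pd.DataFrame:
        if isinstance(data, pd.DataFrame):
            return data
        return records_to_frame(data)

    def _raw_numeric(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for feat, src in NUMERIC_FEATURES:
            col = pd.to_numeric(frame[src], errors="coerce")
            if src in LOG_COLUMNS:
                col = np.log10(col)
            out[feat] = col
        # hydrophobicity: per-scale min-max to [0, 1], single column
        hv = pd.to_numeric(frame["hydrophobicity_value"], errors="coerce")
        hs = frame["hydrophobicity_scale"]
        hydro = pd.Series(np.nan, index=frame.index)
        for scale, (lo, hi) in getattr(
            self, "hydro_range_", {s: (0.0, 1.0) for s in HYDRO_SCALES}
        ).items():
            sel = (hs == scale) & hv.notna()
            hydro[sel] = (hv[sel] - lo) / (hi - lo)
        out["hydrophobicity"] = hydro
        return pd.DataFrame(out, index=frame.index)

    def transform(self, data) -> FeatureMatrix:
        if not self.fitted_:
            raise DatasetError("encoder not fitted")
        frame = self._as_frame(data)
        for group, src, levels in ONEHOT_GROUPS:
            bad = set(frame[src].dropna().unique()) - set(levels)
            if bad:
                raise DatasetError(f"unknown {group} level(s): {sorted(bad)}")

        numeric = self._raw_numeric(frame)
        names: list[str] = []
        cols: list[np.ndarray] = []
        for feat in numeric.columns:
            v = numeric[feat].to_numpy(dtype=float)
            if self.standardize:
                v = (v - self.means_[feat]) / self.stds_[feat]
            names.append(feat)
            cols.append(v)
        # hydrophobicity scale indicator (1 = logKow, 0 = contact angle)
        names.append("hydrophobicity_is_logkow")
        cols.append((frame["hydrophobicity_scale"] == "logKow").to_numpy(float))
        names.append("in_vivo")
        cols.append(frame["in_vivo"].astype(bool).to_numpy(float))

        encoding_map: dict[str, dict[str, int]] = {}
        for group, src, levels in ONEHOT_GROUPS:
            encoding_map[group] = {}
            for level in levels:
                encoding_map[group][level] = len(names)
                names.append(f"{group}={level}")
                cols.append((frame[src] == level).to_numpy(float))

        values = np.column_stack(cols)
        mask = np.isnan(values)
        ids = [str(s) for s in frame["source_id"]] if "source_id" in frame else []
        return FeatureMatrix(
            values=values,
            feature_names=names,
            missing_mask=mask,
            encoding_map=encoding_map,
            transform_log={
                "log10_columns": sorted(LOG_COLUMNS),
                "standardized": self.standardize,
                "means": dict(self.means_),
                "stds": dict(self.stds_),
                "hydro_range": dict(self.hydro_range_),
            },
            ids=ids,
        )

    def fit_transform(self, data) -> FeatureMatrix:
        return self.fit(data).transform(data)


#: model-feature groups for grouped permutation importance, keyed by the
#: descriptor name a practitioner would report
FEATURE_GROUPS = {
    "core_diameter": ["log10_core_diameter"],
    "surface_area": ["log10_surface_area"],
    "volume": ["log10_volume"],
    "sv_ratio": ["sv_ratio"],
    "concentration": ["log10_concentration"],
    "hydrophobicity": ["hydrophobicity", "hydrophobicity_is_logkow"],
    "medium": None,  # one-hot group
    "np_class": None,
    "shape": None,
    "temperature": ["temperature"],
    "contact_time": ["contact_time"],
    "in_vivo": ["in_vivo"],
    "species": None,
    "region": None,
    "sc_thickness": ["sc_thickness"],
    "epidermis_thickness": ["epidermis_thickness"],
    "dermis_thickness": ["dermis_thickness"],
    "hf_density": ["hf_density"],
    "hf_diameter": ["hf_diameter"],
    "lipid_lipophilicity": ["lipid_lipophilicity"],
    "lipid_polarity": ["lipid_polarity"],
}


def feature_group_columns(fm: FeatureMatrix) -> dict[str, list[int]]:
    """Column indices for each named descriptor group in ``fm``."""
    out = {}
    for group, members in FEATURE_GROUPS.items():
        if members is None:
            out[group] = fm.group_columns(group)
        else:
            out[group] = [fm.column(m) for m in members]
    return out


def encode_features(records, config=None, encoder: FeatureEncoder | None = None):
    """Encode records into a :class:`FeatureMatrix`.

    If ``encoder`` is given it must already be fitted (used to project
    hold-out or in-silico data through modelling-set parameters);
    otherwise a new encoder is fitted on ``records`` and returned with
    the matrix.
    """
    standardize = True if config is None else config.get("standardize", True)
    if encoder is None:
        enc = FeatureEncoder(standardize=standardize)
        return enc.fit_transform(records), enc
    return encoder.transform(records), encoder


def depth_labels(data) -> np.ndarray:
    """Depth labels of records/frame as an array of strings."""
    if isinstance(data, pd.DataFrame):
        return data["depth"].to_numpy()
    return np.array([r.depth for r in data])


def depth_to_int(y) -> np.ndarray:
    """Map depth labels to ordinal codes 0 (Surface) .. 4 (Distant)."""
    lut = {c: i for i, c in enumerate(DEPTH_CLASSES)}
    return np.array([lut[v] for v in y], dtype=int)


def int_to_depth(codes) -> np.ndarray:
    return np.array([DEPTH_CLASSES[int(c)] for c in codes])
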