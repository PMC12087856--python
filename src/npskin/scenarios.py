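"""Skin-parameter perturbation scenarios and penetration-route attribution.

Three anatomical routes carry NPs through skin: transappendageal (via
hair follicles), intercellular (through the SC lipid matrix) and
intracellular (through corneocytes).  Which route a population relies on
is inferred by perturbing the skin parameters that gate each route and
watching how the predicted layer occupancy shifts relative to baseline:

* ``reduced_follicles`` — hair-follicle density lowered (transappendageal);
* ``lipophilic_shift`` — SC lipid lipophilicity raised, polarity lowered
  (favours the intercellular route);
* ``polar_shift`` — the opposite lipid change (pushes transport toward
  the intracellular route).

Magnitudes run in 5% steps up to 20%.  Shifts indicate *preferred*
pathways; no route is ever exclusively used, so attribution labels are
always reported together with the underlying occupancy deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from npskin.datamodel import DEPTH_CLASSES, DatasetError, SkinDescriptor
from npskin.applicability import InSilicoPopulation

SCENARIO_IDS = ("baseline", "reduced_follicles", "lipophilic_shift", "polar_shift")
MAGNITUDES = (0, 5, 10, 15, 20)

#: skin fields touched by each scenario and the sign of the change
SCENARIO_EFFECTS = {
    "baseline": {},
    "reduced_follicles": {"hf_density": -1},
    "lipophilic_shift": {"lipid_lipophilicity": +1, "lipid_polarity": -1},
    "polar_shift": {"lipid_lipophilicity": -1, "lipid_polarity": +1},
}

#: route gated by each non-baseline scenario
SCENARIO_ROUTE = {
    "reduced_follicles": "transappendageal",
    "lipophilic_shift": "intercellular",
    "polar_shift": "intracellular",
}

_FIELD_TO_COLUMN = {
    "hf_density": "hf_density_per_cm2",
    "lipid_lipophilicity": "lipid_lipophilicity",
    "lipid_polarity": "lipid_polarity",
}


@dataclass
class ScenarioSpec:
    id: str
    magnitude: int

    def __post_init__(self):
        if self.id not in SCENARIO_IDS:
            raise DatasetError(f"unknown scenario {self.id!r}")
        if self.magnitude not in MAGNITUDES:
            raise DatasetError(f"magnitude must be one of {MAGNITUDES}")
        if self.id == "baseline" and self.magnitude != 0:
            raise DatasetError("baseline has magnitude 0")

    def multipliers(self) -> dict[str, float]:
        return {
            f: 1.0 + sign * self.magnitude / 100.0
            for f, sign in SCENARIO_EFFECTS[self.id].items()
        }


def apply_scenario(skin: SkinDescriptor, spec: ScenarioSpec) -> SkinDescriptor:
    """Multiplicatively perturb only the scenario's skin fields."""
    changes = {}
    for fld, mult in spec.multipliers().items():
        new = getattr(skin, fld) * mult
        if new <= 0:
            raise DatasetError(f"scenario drives {fld} non-positive")
        changes[fld] = new
    return replace(skin, **changes)


@dataclass
class ScenarioResult:
    """Per medium x scenario x magnitude x layer occupancy and delta."""

    table: pd.DataFrame  # columns: medium, scenario, magnitude, layer,
    #                      occupancy_pct, delta_pp
    media: tuple[str, ...]

    def occupancy(self, medium, scenario, magnitude) -> pd.Series:
        t = self.table
        sel = t[(t.medium == medium) & (t.scenario == scenario)
                & (t.magnitude == magnitude)]
        return sel.set_index("layer")["occupancy_pct"]


def run_route_experiment(
    model,
    population: InSilicoPopulation,
    encoder,
    scenarios=None,
    media=("aqueous", "emulsion", "oil"),
) -> ScenarioResult:
    """Predict layer occupancy under every scenario x magnitude per medium.

    The population's skin columns are rescaled per scenario, re-encoded
    through the fitted encoder, and re-classified; occupancy percentages
    per layer (closing to 100 within each cell) are compared against the
    magnitude-0 baseline.  Fully deterministic given model + population.
    """
    if scenarios is None:
        scenarios = [ScenarioSpec("baseline", 0)] + [
            ScenarioSpec(s, m)
            for s in ("reduced_follicles", "lipophilic_shift", "polar_shift")
            for m in (5, 10, 15, 20)
        ]
    frame = population.frame
    rows = []
    for medium in media:
        sub = frame[frame["medium"] == medium]
        if len(sub) == 0:
            raise DatasetError(f"medium group {medium!r} is empty")
        base_occ = None
        for spec in sorted(scenarios, key=lambda s: (s.id != "baseline", s.id,
                                                     s.magnitude)):
            pert = sub.copy()
            for fld, mult in spec.multipliers().items():
                pert[_FIELD_TO_COLUMN[fld]] = pert[_FIELD_TO_COLUMN[fld]] * mult
            fm = encoder.transform(pert)
            pred = model.predict(np.nan_to_num(fm.values, nan=0.0))
            occ = pd.Series(
                {c: 100.0 * float(np.mean(pred == c)) for c in DEPTH_CLASSES}
            )
            if spec.id == "baseline":
                base_occ = occ
            if base_occ is None:
                raise DatasetError("scenario list must include the baseline")
            for layer in DEPTH_CLASSES:
                rows.append({
                    "medium": medium,
                    "scenario": spec.id,
                    "magnitude": spec.magnitude,
                    "layer": layer,
                    "occupancy_pct": occ[layer],
                    "delta_pp": occ[layer] - base_occ[layer],
                })
    return ScenarioResult(table=pd.DataFrame(rows), media=tuple(media))


def route_attribution(
    result: ScenarioResult, threshold_pp: float = 1.0
) -> pd.DataFrame:
    """Rule-based route preference per medium, reported with its deltas.

    A medium is labelled as relying on a route when the corresponding
    scenario moves any layer's occupancy by at least ``threshold_pp``
    percentage points at the strongest magnitude; with no sensitivity
    anywhere the label is "no inferred preference".
    """
    t = result.table
    needed = set(SCENARIO_ROUTE) - set(t["scenario"].unique())
    if needed:
        raise DatasetError(f"result missing scenarios: {sorted(needed)}")
    rows = []
    for medium in result.media:
        sens = {}
        for scenario, route in SCENARIO_ROUTE.items():
            sel = t[(t.medium == medium) & (t.scenario == scenario)]
            sens[route] = float(sel["delta_pp"].abs().max())
        labels = [r for r, s in sens.items() if s >= threshold_pp]
        rows.append({
            "medium": medium,
            "transappendageal_max_delta_pp": sens["transappendageal"],
            "intercellular_max_delta_pp": sens["intercellular"],
            "intracellular_max_delta_pp": sens["intracellular"],
            "preferred_routes": ", ".join(labels) if labels
            else "no inferred preference",
        })
    return pd.DataFrame(rows)
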