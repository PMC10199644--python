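"""Individual-tree biomass component models of the Marklund family.

Each (species, component) pair has a fixed log-linear model form built on the
saturating diameter transform D/(D+k):

  form 1:  ln(comp) = b0 + b1 * D/(D+k)
  form 2:  ln(comp) = b0 + b1 * D/(D+k) + b2 * ln(H)
  form 3:  ln(comp) = b0 + b1 * D/(D+k) + b2 * H + b3 * ln(H)

with D in cm, H in m and component dry mass in kg.  Birch lacks observations
for stump, foliage and roots: its stump model delegates to pine, and foliage /
fine roots / coarse roots are fixed ratios of its predicted stem wood.

Models are refitted by OLS on the log scale so that the coefficient covariance
matrix (classical sigma^2 (X'X)^-1) is available for parametric bootstrapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import AGB_COMPONENTS, COMPONENTS, SPECIES

__all__ = [
    "FORM_TABLE",
    "BIRCH_RATIOS",
    "AllometricModel",
    "AllometricModelSet",
    "component_form_lookup",
    "design_matrix",
    "fit_allometric_models",
    "predict_components",
]

#: (form, k) per species and component; None marks birch's delegated/ratio cells.
FORM_TABLE: dict[str, dict[str, tuple[int, float] | None]] = {
    "spruce": {
        "SW": (3, 14), "BR": (3, 13), "DB": (3, 18), "SB": (3, 15),
        "SU": (1, 17), "FL": (2, 12), "RF": (1, 12), "RC": (1, 8),
    },
    "pine": {
        "SW": (3, 14), "BR": (2, 10), "DB": (3, 10), "SB": (2, 16),
        "SU": (1, 15), "FL": (3, 7), "RF": (1, 10), "RC": (1, 9),
    },
    "birch": {
        "SW": (2, 11), "BR": (1, 10), "DB": (3, 30), "SB": (2, 14),
        "SU": None, "FL": None, "RF": None, "RC": None,
    },
}

#: Birch components expressed as ratios of predicted stem wood mass.
BIRCH_RATIOS = {"FL": 0.011 / 0.52, "RF": 0.042 / 0.52, "RC": 0.042 / 0.52}

#: Birch components delegated to the pine model.
BIRCH_DELEGATED = ("SU",)


def component_form_lookup(species: str, component: str):
    """Return ``("form", form, k)``, ``("delegate", "pine")`` or ``("ratio", r)``.

    The birch branch column is branches-plus-foliage; see the model-set
    convention flags for how it enters above-ground totals.
    """
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}")
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    cell = FORM_TABLE[species][component]
    if cell is not None:
        return ("form", cell[0], cell[1])
    if component in BIRCH_DELEGATED:
        return ("delegate", "pine")
    return ("ratio", BIRCH_RATIOS[component])


def design_matrix(form: int, k: float, d: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Design matrix (with intercept) for a given model form."""
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(d <= 0):
        raise ValueError("D must be positive")
    cols = [np.ones_like(d), d / (d + k)]
    if form == 2:
        cols.append(np.log(h))
    elif form == 3:
        cols += [h, np.log(h)]
    elif form != 1:
        raise ValueError(f"unknown form {form}")
    return np.column_stack(cols)


@dataclass
class AllometricModel:
    species: str
    component: str
    form: int
    k: float
    beta: np.ndarray
    cov: np.ndarray
    resid_sd: float
    n_obs: int = 0

    def linear_predictor(self, d, h) -> np.ndarray:
        return design_matrix(self.form, self.k, np.atleast_1d(d), np.atleast_1d(h)) @ self.beta

    def predict(self, d, h) -> np.ndarray:
        """Predicted component mass, kg (naive back-transform by default)."""
        return np.exp(self.linear_predictor(d, h))


@dataclass
class AllometricModelSet:
    """All fitted (species, component) models plus the birch conventions.

    ``birch_fl_in_agb``: if False (default), the fitted birch BR model is read
    as branches-plus-foliage and counts once in above-ground totals, while the
    ratio-derived FL is used only where litter chemistry needs a foliage mass.
    """

    models: dict[tuple[str, str], AllometricModel] = field(default_factory=dict)
    birch_fl_in_agb: bool = False
    bias_correction: bool = False

    def get(self, species: str, component: str) -> AllometricModel:
        rule = component_form_lookup(species, component)
        if rule[0] == "delegate":
            return self.models[(rule[1], component)]
        return self.models[(species, component)]

    def to_json(self) -> str:
        out = {}
        for (sp, comp), m in self.models.items():
            out[f"{sp}/{comp}"] = {
                "form": m.form, "k": m.k, "beta": m.beta.tolist(),
                "cov": m.cov.tolist(), "resid_sd": m.resid_sd, "n_obs": m.n_obs,
            }
        return json.dumps(
            {"models": out, "birch_fl_in_agb": self.birch_fl_in_agb,
             "bias_correction": self.bias_correction}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AllometricModelSet":
        doc = json.loads(text)
        models = {}
        for key, m in doc["models"].items():
            sp, comp = key.split("/")
            models[(sp, comp)] = AllometricModel(
                sp, comp, int(m["form"]), float(m["k"]), np.asarray(m["beta"]),
                np.asarray(m["cov"]), float(m["resid_sd"]), int(m.get("n_obs", 0)))
        return cls(models, doc.get("birch_fl_in_agb", False), doc.get("bias_correction", False))


def fit_allometric_models(trees: pd.DataFrame, **set_kwargs) -> AllometricModelSet:
    """Refit every component model by OLS on the log scale.

    ``trees`` needs columns species, D, H and one column per component (kg;
    NaN where the component was not measured).  Birch's delegated/ratio
    components are skipped.  A rank-deficient or undersized design raises
    ``ValueError`` naming the (species, component) pair.
    """
    mset = AllometricModelSet(**set_kwargs)
    for species in SPECIES:
        sub = trees[trees["species"] == species]
        for comp in COMPONENTS:
            rule = component_form_lookup(species, comp)
            if rule[0] != "form":
                continue
            _, form, k = rule
            rows = sub.dropna(subset=[comp])
            rows = rows[rows[comp] > 0]
            x = design_matrix(form, k, rows["D"].to_numpy(), rows["H"].to_numpy())
            if len(rows) < x.shape[1] + 2:
                raise ValueError(f"too few observations for ({species}, {comp})")
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise ValueError(f"rank-deficient design for ({species}, {comp})")
            res = sm.OLS(np.log(rows[comp].to_numpy()), x).fit()
            mset.models[(species, comp)] = AllometricModel(
                species, comp, form, k, res.params, res.cov_params(),
                float(np.sqrt(res.scale)), len(rows))
    return mset


def predict_components(
    mset: AllometricModelSet, d: float, h: float, species: str
) -> pd.Series:
    """Predict all eight component dry masses (kg) for one mean tree.

    Birch SU uses the pine model; birch FL/RF/RC are fixed ratios of the
    predicted birch stem wood.  With ``bias_correction`` enabled, fitted-model
    predictions are multiplied by exp(resid_sd^2 / 2).
    """
    if d <= 0:
        raise ValueError("D must be positive")
    if h < 1.3:
        raise ValueError("H must be at least breast height (1.3 m)")
    out = {}
    for comp in COMPONENTS:
        rule = component_form_lookup(species, comp)
        if rule[0] == "ratio":
            continue
        model = mset.get(species, comp)
        val = float(model.predict(d, h)[0])
        if mset.bias_correction:
            val *= float(np.exp(0.5 * model.resid_sd**2))
        out[comp] = val
    for comp, ratio in BIRCH_RATIOS.items():
        if species == "birch":
            out[comp] = ratio * out["SW"]
    return pd.Series([out[c] for c in COMPONENTS], index=list(COMPONENTS))


def predict_components_vec(
    mset: AllometricModelSet, d: np.ndarray, h: np.ndarray, species: str
) -> np.ndarray:
    """Vectorised component prediction: (n, 8) kg matrix for one species."""
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    out = np.empty((len(d), len(COMPONENTS)))
    sw = None
    for j, comp in enumerate(COMPONENTS):
        rule = component_form_lookup(species, comp)
        if rule[0] == "ratio":
            out[:, j] = np.nan  # filled from SW below
            continue
        model = mset.get(species, comp)
        vals = np.exp(model.linear_predictor(d, h))
        if mset.bias_correction:
            vals = vals * np.exp(0.5 * model.resid_sd**2)
        out[:, j] = vals
        if comp == "SW":
            sw = vals
    for comp, ratio in BIRCH_RATIOS.items():
        if species == "birch":
            out[:, COMPONENTS.index(comp)] = ratio * sw
    return out


def agb_bgb_split(components: pd.Series, species: str, mset: AllometricModelSet | None = None) -> tuple[float, float]:
    """Total above- and below-ground dry mass (kg) under the set's conventions.

    For birch with the default convention the BR column already contains
    foliage, so FL is excluded from the above-ground sum to avoid double
    counting.
    """
    agb_comps = list(AGB_COMPONENTS)
    if species == "birch" and (mset is None or not mset.birch_fl_in_agb):
        agb_comps.remove("FL")
    agb = float(components[agb_comps].sum())
    bgb = float(components[["RF", "RC"]].sum())
    return agb, bgb
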