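"""The seven methane-yield prediction equations.

Model 1c is derived from rumen fermentation stoichiometry: fermenting
hexose to acetate or butyrate releases metabolic hydrogen that is captured
as methane, while fermentation to propionate consumes hydrogen, giving

    CH4P = 0.50*C2 - 0.25*C3 + 0.50*C4        (moles)

for C2/C3/C4 moles of acetate/propionate/total butyrate.  Dividing by
100 mol total VFA expresses the same balance on molar proportions
(A, P, B), and assuming each kg of dry matter eaten ferments to ``c``
moles of total VFA converts it to a methane yield in g CH4/kg DMI:

    MY = 16 * (0.50*A - 0.25*P + 0.50*B) * c / 100

with 16 g/mol the molar mass of methane and ``c`` the single free
parameter.  Models 2-7 are empirical linear forms in A, P, B, the ratios
A/P and (A+B)/P, the reciprocal 1/P, and the propionate concentration [P].

The module also carries a registry of the published calibrated
coefficients for all seven forms, obtained by mixed-effects meta-analysis
of 215 individual dairy-cow records from seven experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import VFAProfile

__all__ = [
    "ModelForm",
    "FittedEquation",
    "MODEL_FORMS",
    "FORM_IDS",
    "get_form",
    "stoichiometric_methane",
    "design_vector",
    "predict",
    "published_equation",
]

#: Molar mass of methane, g/mol.
CH4_MOLAR_MASS = 16.0


@dataclass(frozen=True)
class ModelForm:
    """Structure of one prediction equation.

    ``covariate_spec`` names the covariate transforms in order;
    an intercept column (constant 1) is appended last when
    ``has_intercept`` is set.  ``parameter_names`` follow the
    conventional symbols (c, d..f, g/h, i/j, k/m, n/q, s/t).
    """

    form_id: str
    covariate_spec: tuple[str, ...]
    has_intercept: bool
    parameter_names: tuple[str, ...]
    description: str

    @property
    def n_parameters(self) -> int:
        return len(self.covariate_spec) + int(self.has_intercept)

    @property
    def requires_conc(self) -> bool:
        return "propionate_conc" in self.covariate_spec


MODEL_FORMS: dict[str, ModelForm] = {
    "M1C": ModelForm(
        "M1C",
        ("stoichiometric_yield",),
        False,
        ("c",),
        "MY = 16*(0.50A - 0.25P + 0.50B)*c/100",
    ),
    "M2": ModelForm(
        "M2",
        ("acetate", "minus_propionate", "butyrate"),
        False,
        ("d", "e", "f"),
        "MY = dA - eP + fB",
    ),
    "M3": ModelForm("M3", ("a_over_p",), True, ("g", "h"), "MY = g(A/P) + h"),
    "M4": ModelForm("M4", ("ab_over_p",), True, ("i", "j"), "MY = i(A+B)/P + j"),
    "M5": ModelForm("M5", ("propionate",), True, ("k", "m"), "MY = kP + m"),
    "M6": ModelForm("M6", ("propionate_conc",), True, ("n", "q"), "MY = n[P] + q"),
    "M7": ModelForm("M7", ("inv_propionate",), True, ("s", "t"), "MY = s/P + t"),
}

FORM_IDS = tuple(MODEL_FORMS)


def get_form(form_id: str | ModelForm) -> ModelForm:
    """Resolve a form id (case-insensitive; "4" or "M4") to its ModelForm."""
    if isinstance(form_id, ModelForm):
        return form_id
    key = str(form_id).upper()
    if not key.startswith("M"):
        key = "M" + key
    if key == "M1":
        key = "M1C"
    if key not in MODEL_FORMS:
        raise KeyError(
            f"unknown model form {form_id!r}; expected one of {', '.join(FORM_IDS)}"
        )
    return MODEL_FORMS[key]


def stoichiometric_methane(c2: float, c3: float, c4: float) -> float:
    """Moles of methane implied by fermentation-balance stoichiometry.

    ``0.50*c2 - 0.25*c3 + 0.50*c4`` for c2/c3/c4 moles of acetate,
    propionate and total butyrate.  The same expression applied to molar
    proportions (mol/100 mol total VFA) gives the methane yield per
    100 mol total VFA.  A propionate-dominant input can make the balance
    negative; the value is returned as-is with a warning, since a
    negative mole balance signals inputs outside the model's domain
    rather than a quantity to clip.
    """
    if c2 < 0 or c3 < 0 or c4 < 0:
        raise ValueError(f"VFA quantities must be >= 0, got ({c2}, {c3}, {c4})")
    out = 0.50 * c2 - 0.25 * c3 + 0.50 * c4
    if out < 0:
        warnings.warn(
            f"stoichiometric methane balance is negative ({out:.4f} mol) for "
            f"propionate-dominant input ({c2}, {c3}, {c4})",
            stacklevel=2,
        )
    return out


def _covariate(name: str, profile: VFAProfile) -> float:
    a, p, b = profile.acetate, profile.propionate, profile.butyrate
    if name == "stoichiometric_yield":
        return CH4_MOLAR_MASS * (0.50 * a - 0.25 * p + 0.50 * b) / 100.0
    if name == "acetate":
        return a
    if name == "minus_propionate":
        return -p
    if name == "butyrate":
        return b
    if name == "a_over_p":
        return a / p
    if name == "ab_over_p":
        return (a + b) / p
    if name == "propionate":
        return p
    if name == "inv_propionate":
        return 1.0 / p
    if name == "propionate_conc":
        if profile.propionate_conc is None:
            raise ValueError(
                "model M6 requires the field 'propionate_conc' (mmol/L), "
                "which is not set on this profile"
            )
        return profile.propionate_conc
    raise ValueError(f"unknown covariate transform {name!r}")


def design_vector(form: str | ModelForm, profile: VFAProfile) -> np.ndarray:
    """Covariates of ``form`` at ``profile``, intercept column (1.0) last."""
    form = get_form(form)
    values = [_covariate(name, profile) for name in form.covariate_spec]
    if form.has_intercept:
        values.append(1.0)
    return np.asarray(values, dtype=float)


@dataclass
class FittedEquation:
    """A model form with estimated (or published) coefficients.

    ``variance_components`` are the random-intercept variances
    (experiment, treatment-within-experiment, cow/residual) in
    (g CH4/kg DMI)^2, or ``None`` when not available.  ``metadata`` holds
    fitter diagnostics (method, log-likelihood, convergence flag).
    """

    form: ModelForm
    coefficients: np.ndarray
    standard_errors: np.ndarray | None = None
    variance_components: tuple[float, float, float] | None = None
    source: str = "fitted"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.form.n_parameters:
            raise ValueError(
                f"{self.form.form_id} expects {self.form.n_parameters} "
                f"coefficients, got {self.coefficients.size}"
            )
        if self.standard_errors is not None:
            self.standard_errors = np.asarray(self.standard_errors, dtype=float)
            if self.standard_errors.size != self.coefficients.size:
                raise ValueError("standard_errors length mismatch")
        if self.variance_components is not None:
            if len(self.variance_components) != 3 or any(
                v < 0 for v in self.variance_components
            ):
                raise ValueError(
                    "variance_components must be three non-negative values"
                )

    def predict(self, profile: VFAProfile) -> float:
        return predict(self, profile)

    def to_dict(self) -> dict:
        return {
            "form_id": self.form.form_id,
            "model": self.form.description,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": (
                None
                if self.standard_errors is None
                else self.standard_errors.tolist()
            ),
            "variance_components": (
                None
                if self.variance_components is None
                else list(self.variance_components)
            ),
            "source": self.source,
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedEquation":
        return cls(
            form=get_form(payload["form_id"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            standard_errors=(
                None
                if payload.get("standard_errors") is None
                else np.asarray(payload["standard_errors"], dtype=float)
            ),
            variance_components=(
                None
                if payload.get("variance_components") is None
                else tuple(payload["variance_components"])
            ),
            source=payload.get("source", "fitted"),
            metadata=payload.get("metadata", {}),
        )


def predict(eq: FittedEquation, profile: VFAProfile) -> float:
    """Fixed-effect prediction of methane yield (g CH4/kg DMI)."""
    return float(design_vector(eq.form, profile) @ eq.coefficients)


# Published calibrated coefficients (estimate, standard error per parameter),
# fitted to the pooled development data of 215 cow records.  Variance
# components of the deviations were reported for M4 (and stated similar for
# M3 and M7) only: 1.7 experiment, 1.5 treatment-within-experiment, 6.9 cow.
_PUBLISHED_VARIANCE_COMPONENTS = (1.7, 1.5, 6.9)

_PUBLISHED: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "M1C": ((3.98,), (0.15,)),
    "M2": ((0.30, 0.22, 0.48), (0.042, 0.055, 0.16)),
    "M3": ((4.08, 7.05), (0.36, 1.40)),
    "M4": ((3.28, 7.60), (0.29, 1.28)),
    "M5": ((-0.57, 32.3), (0.057, 1.4)),
    "M6": ((-0.24, 26.1), (0.035, 1.3)),
    "M7": ((316.0, 4.4), (28.0, 1.5)),
}


def published_equation(form_id: str | ModelForm) -> FittedEquation:
    """The published calibrated equation for one of the seven forms."""
    form = get_form(form_id)
    coefficients, standard_errors = _PUBLISHED[form.form_id]
    return FittedEquation(
        form=form,
        coefficients=np.asarray(coefficients),
        standard_errors=np.asarray(standard_errors),
        variance_components=(
            _PUBLISHED_VARIANCE_COMPONENTS
            if form.form_id in ("M3", "M4", "M7")
            else None
        ),
        source="published",
    )
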