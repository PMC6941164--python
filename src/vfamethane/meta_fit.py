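"""Three-level mixed-effects meta-analysis of a prediction equation.

Each equation's fixed effects are estimated from individual-cow data
pooled across experiments under the model

    MY_ijk = x_ijk' beta + u_i + v_ij + e_ijk

with independent random intercepts u_i ~ N(0, s2_experiment) for
experiment, v_ij ~ N(0, s2_treatment) for treatment within experiment,
and residual e_ijk ~ N(0, s2_cow) for cow.  Estimation is restricted
maximum likelihood (REML) by default, via :class:`statsmodels MixedLM`
with the experiment as the grouping factor, a random intercept per group
and a variance component for treatment within experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .data_model import Dataset
from .equations import FittedEquation, ModelForm, design_vector, get_form

__all__ = [
    "FitOptions",
    "ConvergenceError",
    "SingularDesignError",
    "fit_meta",
    "fit_all",
    "restricted_loglike",
]


@dataclass(frozen=True)
class FitOptions:
    """Options for the mixed-effects fit.

    method
        "reml" (default) or "ml".
    max_iterations
        Optimizer iteration cap.
    convergence_tol
        Relative log-likelihood convergence tolerance.
    variance_floor
        Lower bound applied to the reported variance components
        (the optimizer itself constrains them to be non-negative).
    constrain_upper_zero
        Fix the experiment and treatment variances at zero, reducing the
        fit to ordinary least squares on the pooled records.  Used for
        sensitivity checks.
    """

    method: str = "reml"
    max_iterations: int = 500
    convergence_tol: float = 1e-8
    variance_floor: float = 0.0
    constrain_upper_zero: bool = False

    def __post_init__(self) -> None:
        if self.method.lower() not in ("reml", "ml"):
            raise ValueError(f"method must be 'reml' or 'ml', got {self.method!r}")
        if self.convergence_tol <= 0 or self.max_iterations <= 0:
            raise ValueError("tolerances and iteration caps must be positive")
        if self.variance_floor < 0:
            raise ValueError("variance_floor must be >= 0")


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


def _design_frame(data: Dataset, form: ModelForm) -> tuple[pd.DataFrame, list[str]]:
    rows = []
    for rec in data:
        x = design_vector(form, rec.vfa)
        rows.append(
            [rec.experiment_id, f"{rec.experiment_id}::{rec.treatment_id}"]
            + list(x)
            + [rec.methane_yield]
        )
    x_cols = [f"x{i}" for i in range(form.n_parameters)]
    frame = pd.DataFrame(rows, columns=["experiment", "exp_trt"] + x_cols + ["my"])
    return frame, x_cols


def _check_preconditions(data: Dataset, form: ModelForm) -> None:
    if len(data) == 0:
        raise ValueError("cannot fit an empty dataset")
    if len(data) <= form.n_parameters:
        raise ValueError(
            f"{len(data)} records cannot identify {form.n_parameters} "
            f"fixed effects plus variance components"
        )


def fit_meta(
    data: Dataset, form: str | ModelForm, options: FitOptions | None = None
) -> FittedEquation:
    """Fit one model form to a dataset by mixed-effects meta-analysis.

    Returns a :class:`FittedEquation` with REML (or ML) fixed-effect
    estimates, their standard errors from the observed information, and
    the estimated variance components (experiment, treatment within
    experiment, cow).  Fit diagnostics (method, log-likelihood,
    convergence flag) are stored in ``metadata``.

    Raises
    ------
    SingularDesignError
        The covariates are collinear (e.g. a constant covariate together
        with an intercept).
    ConvergenceError
        The likelihood optimizer did not converge; the exception carries
        the last iterate.
    """
    form = get_form(form)
    options = options or FitOptions()
    _check_preconditions(data, form)

    frame, x_cols = _design_frame(data, form)
    x_matrix = frame[x_cols].to_numpy()
    if np.linalg.matrix_rank(x_matrix) < len(x_cols):
        raise SingularDesignError(
            f"design matrix for {form.form_id} is rank deficient "
            f"(constant or collinear covariates)"
        )

    # Degenerate noiseless case: when the response is an exact linear
    # function of the covariates the REML surface has no interior optimum
    # (residual variance -> 0); the generalized least squares solution is
    # then the plain least-squares solution with all components at zero.
    y = frame["my"].to_numpy()
    beta_ls, *_ = np.linalg.lstsq(x_matrix, y, rcond=None)
    rss = float(np.sum((y - x_matrix @ beta_ls) ** 2))
    scale_ref = float(np.sum((y - y.mean()) ** 2)) if len(y) > 1 else 1.0
    if rss <= 1e-12 * max(scale_ref, 1.0):
        return FittedEquation(
            form=form,
            coefficients=beta_ls,
            standard_errors=np.zeros_like(beta_ls),
            variance_components=(0.0, 0.0, 0.0),
            source="fitted",
            metadata={
                "method": options.method.lower(),
                "converged": True,
                "degenerate_noiseless": True,
                "loglike": float("inf"),
                "n_records": len(data),
                "n_experiments": data.n_experiments,
                "n_treatments": data.n_treatments,
            },
        )

    model = smf.mixedlm(
        "my ~ 0 + " + " + ".join(x_cols),
        frame,
        groups="experiment",
        re_formula="1",
        vc_formula={"treatment": "0 + C(exp_trt)"},
    )

    fit_kwargs: dict = {
        "reml": options.method.lower() == "reml",
        "maxiter": options.max_iterations,
        "method": ["lbfgs", "bfgs", "cg", "powell"],
    }
    if options.constrain_upper_zero:
        k_fe = len(x_cols)
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe),
            cov_re=np.zeros((1, 1)),
            vcomp=np.zeros(model.k_vc),
        )
        # pinned at a negligible ratio (an exact zero makes the random-effect
        # covariance non-invertible inside the likelihood); the GLS solution
        # is then the pooled OLS solution to within 1e-10
        start = MixedLMParams.from_components(
            fe_params=np.zeros(k_fe),
            cov_re=np.asarray([[1e-10]]),
            vcomp=np.full(model.k_vc, 1e-10),
        )
        fit_kwargs["free"] = free
        fit_kwargs["start_params"] = start

    with warnings.catch_warnings():
        # boundary estimates (a variance pinned at 0) are legitimate and
        # handled below; suppress the optimizer's chatter about them
        warnings.simplefilter("ignore")
        result = model.fit(**fit_kwargs)

    if not getattr(result, "converged", True):
        raise ConvergenceError(
            f"mixed-effects fit for {form.form_id} did not converge within "
            f"{options.max_iterations} iterations",
            last_params=np.asarray(result.params),
        )

    floor = options.variance_floor
    s2_experiment = max(float(result.cov_re.iloc[0, 0]), floor)
    s2_treatment = max(float(result.vcomp[0]), floor)
    s2_cow = max(float(result.scale), floor)
    if options.constrain_upper_zero:
        s2_experiment = s2_treatment = 0.0

    return FittedEquation(
        form=form,
        coefficients=np.asarray(result.fe_params, dtype=float),
        standard_errors=np.asarray(result.bse_fe, dtype=float),
        variance_components=(s2_experiment, s2_treatment, s2_cow),
        source="fitted",
        metadata={
            "method": options.method.lower(),
            "converged": bool(result.converged),
            "loglike": float(result.llf),
            "n_records": len(data),
            "n_experiments": data.n_experiments,
            "n_treatments": data.n_treatments,
        },
    )


def fit_all(
    data: Dataset,
    options: FitOptions | None = None,
    forms=None,
) -> dict[str, FittedEquation]:
    """Fit every fittable form; failures are warned about, not fatal.

    Forms requiring the propionate concentration (M6) are skipped with a
    warning when the column is absent from the data.  A form whose fit
    raises is likewise reported by warning and omitted from the result.
    """
    from .equations import FORM_IDS

    options = options or FitOptions()
    wanted = [get_form(f) for f in (forms or FORM_IDS)]
    fits: dict[str, FittedEquation] = {}
    for form in wanted:
        if form.requires_conc and any(
            rec.vfa.propionate_conc is None for rec in data
        ):
            warnings.warn(
                f"skipping {form.form_id}: propionate_conc not set on all records",
                stacklevel=2,
            )
            continue
        try:
            fits[form.form_id] = fit_meta(data, form, options)
        except Exception as err:  # noqa: BLE001 - per-form isolation
            warnings.warn(f"fit of {form.form_id} failed: {err}", stacklevel=2)
    return fits


def restricted_loglike(
    data: Dataset,
    form: str | ModelForm,
    exp_ratio: float,
    trt_ratio: float,
    options: FitOptions | None = None,
) -> float:
    """Profiled (restricted) log-likelihood at given variance ratios.

    ``exp_ratio`` and ``trt_ratio`` are the experiment and treatment
    variance components expressed relative to the residual variance, the
    parameterization in which the likelihood profiles out both the fixed
    effects and the residual scale.  Used to verify local optimality of a
    fit: the value at the fitted ratios must dominate perturbations.
    """
    form = get_form(form)
    options = options or FitOptions()
    frame, x_cols = _design_frame(data, form)
    model = smf.mixedlm(
        "my ~ 0 + " + " + ".join(x_cols),
        frame,
        groups="experiment",
        re_formula="1",
        vc_formula={"treatment": "0 + C(exp_trt)"},
    )
    params = MixedLMParams.from_components(
        cov_re=np.asarray([[max(exp_ratio, 1e-12)]]),
        vcomp=np.asarray([max(trt_ratio, 1e-12)] * model.k_vc),
    )
    # loglike is usually reached via fit(), which initializes these
    model.reml = options.method.lower() == "reml"
    model.cov_pen = None
    model.fe_pen = None
    model._cov_sing = 0
    return float(model.loglike(params, profile_fe=True))
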