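"""Hierarchical synthetic VFA / methane-yield data generator.

Emulates the structure of the model-development data: 7 experiments,
24 treatments, 215 individual cows, with methane yield generated as

    MY = f(profile; true equation) + u_experiment + v_treatment + e_cow

where the three random intercepts have the study's variance components
(1.7, 1.5 and 6.9 (g CH4/kg DMI)^2 by default).  VFA profiles are drawn
compositionally: propionate and butyrate come from truncated normal
marginals (location recentred so the post-truncation mean equals the
configured mean), minor VFA are held near 6.6 mol/100 mol, and acetate
takes the balance, which induces the negative acetate-propionate
association the compositional constraint requires.  Diet (treatment
level) effects shift the propionate mean — concentrate feeding chiefly
moves propionate — with spread ``diet_shift_sd``, and are compensated in
acetate through the balance.

The generator is fully reproducible: every experiment, treatment and cow
draws from its own seeded substream, so adding cows or treatments does
not perturb earlier draws.

Caveat: the total VFA concentration (needed only by the propionate
concentration model M6) defaults to 100 +/- 15 mmol/L, a plausible rumen
value chosen for this package; the development study reports no
concentration distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .data_model import CowRecord, Dataset, VFAProfile
from .equations import FittedEquation, get_form, predict, published_equation

__all__ = [
    "SimulationConfig",
    "simulate_dataset",
    "calibrate_spread",
    "make_fixture",
    "UnattainableSpreadError",
    "FIXTURE_NAMES",
]

# Cow counts per treatment follow the development data's experiment plan;
# the study reports 215 records from these experiments, two fewer than the
# plan's cow total, so the two largest treatment groups are reduced by one.
_DEFAULT_COWS = (
    (12, 10, 10),
    (8, 7, 8, 7),
    (8, 7, 8, 8),
    (12, 10, 10),
    (13, 13),
    (8, 8, 8, 8),
    (8, 8, 8, 8),
)

#: Default diet-shift spread on the propionate mean (mol/100 mol), the
#: value returned by :func:`calibrate_spread` for a total methane-yield
#: standard deviation of 4.81 g/kg DMI under the default configuration.
_CALIBRATED_DIET_SHIFT_SD = 2.1


class UnattainableSpreadError(ValueError):
    """The requested total methane-yield spread cannot be reached."""

    def __init__(self, message: str, closest: float):
        super().__init__(message)
        self.closest = closest


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the development study's design: the experiment /
    treatment / cow layout, the published Model 4 equation as the true
    fixed-effect surface, the reported variance components, and truncated
    normal VFA marginals with the reported means, SDs and ranges.
    """

    n_experiments: int = 7
    treatments_per_experiment: tuple[int, ...] = (3, 4, 4, 3, 2, 4, 4)
    cows_per_treatment: tuple[tuple[int, ...], ...] = _DEFAULT_COWS
    true_form: str = "M4"
    true_coefficients: tuple[float, ...] | None = None
    variance_components: tuple[float, float, float] = (1.7, 1.5, 6.9)
    vfa_means: tuple[float, float, float] = (63.3, 20.2, 9.9)
    vfa_sds: tuple[float, float, float] = (4.53, 5.44, 4.02)
    vfa_bounds: tuple[tuple[float, float], ...] = (
        (51.3, 70.7),
        (12.9, 40.2),
        (0.7, 15.6),
    )
    minor_vfa_mean: float = 6.6
    minor_vfa_sd: float = 0.5
    diet_shift_sd: float = _CALIBRATED_DIET_SHIFT_SD
    total_vfa_conc_mean_sd: tuple[float, float] | None = (100.0, 15.0)
    independent_vfa_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if len(self.treatments_per_experiment) != self.n_experiments:
            raise ValueError(
                "treatments_per_experiment length must equal n_experiments"
            )
        if len(self.cows_per_treatment) != self.n_experiments:
            raise ValueError("cows_per_treatment length must equal n_experiments")
        for n_trt, counts in zip(
            self.treatments_per_experiment, self.cows_per_treatment
        ):
            if len(counts) != n_trt:
                raise ValueError(
                    "cows_per_treatment rows must match treatments_per_experiment"
                )
            if any(c < 1 for c in counts):
                raise ValueError("cow counts must be >= 1")
        if any(sd <= 0 for sd in self.vfa_sds):
            raise ValueError("vfa_sds must be > 0")
        if any(v < 0 for v in self.variance_components):
            raise ValueError("variance_components must be >= 0")
        if self.diet_shift_sd < 0:
            raise ValueError("diet_shift_sd must be >= 0")
        for mean, (lo, hi) in zip(self.vfa_means, self.vfa_bounds):
            if not lo < mean < hi:
                raise ValueError(
                    f"bounds ({lo}, {hi}) must contain the mean {mean}"
                )

    @property
    def n_treatments(self) -> int:
        return sum(self.treatments_per_experiment)

    @property
    def n_cows(self) -> int:
        return sum(sum(c) for c in self.cows_per_treatment)

    def true_equation(self) -> FittedEquation:
        form = get_form(self.true_form)
        if self.true_coefficients is None:
            return published_equation(form)
        return FittedEquation(
            form=form,
            coefficients=np.asarray(self.true_coefficients, dtype=float),
            source="published",
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@lru_cache(maxsize=16384)
def _recentred_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose post-truncation mean is ``mean``."""
    if hi < mean - 6 * sd or lo > mean + 6 * sd:
        raise ValueError(
            f"truncation bounds ({lo}, {hi}) infeasible for mean {mean} "
            f"(outside mean +/- 6 sd)"
        )

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd)) - mean

    return float(optimize.brentq(gap, lo - 8 * sd, hi + 8 * sd, xtol=1e-10))


def _draw_truncnorm(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    # mean is quantized so the recentring solve caches across treatments
    mean = round(mean, 2)
    loc = _recentred_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Generate one reproducible hierarchical dataset.

    Identical configs (including ``seed``) produce bit-identical
    datasets.  Every generated profile satisfies the VFA invariants and
    the configured truncation bounds for propionate and butyrate
    (acetate is the compositional balance and may exceed its nominal
    bounds slightly).
    """
    truth = config.true_equation()
    s2_exp, s2_trt, s2_cow = config.variance_components
    mean_a, mean_p, mean_b = config.vfa_means
    sd_a, sd_p, sd_b = config.vfa_sds
    bounds_a, bounds_p, bounds_b = config.vfa_bounds
    seed = int(config.seed)

    records: list[CowRecord] = []
    for i in range(config.n_experiments):
        rng_exp = _rng(seed, 1, i)
        u = rng_exp.normal(0.0, math.sqrt(s2_exp))
        for j in range(config.treatments_per_experiment[i]):
            rng_trt = _rng(seed, 2, i, j)
            v = rng_trt.normal(0.0, math.sqrt(s2_trt))
            shift = rng_trt.normal(0.0, config.diet_shift_sd)
            # keep the shifted treatment mean inside the truncation window
            lo_p, hi_p = bounds_p
            p_target = float(
                np.clip(mean_p + shift, lo_p + 0.2 * sd_p, hi_p - 0.7 * sd_p)
            )
            for k in range(config.cows_per_treatment[i][j]):
                rng_cow = _rng(seed, 3, i, j, k)
                p = _draw_truncnorm(p_target, sd_p, lo_p, hi_p, rng_cow)
                b = _draw_truncnorm(mean_b, sd_b, *bounds_b, rng_cow)
                minor = float(
                    np.clip(
                        rng_cow.normal(config.minor_vfa_mean, config.minor_vfa_sd),
                        0.5,
                        20.0,
                    )
                )
                if config.independent_vfa_mode:
                    a = _draw_truncnorm(mean_a, sd_a, *bounds_a, rng_cow)
                    total = a + p + b + minor
                    if total > 100.0:  # renormalize the majors into the balance
                        scale = (100.0 - minor) / (a + p + b)
                        a, p, b = a * scale, p * scale, b * scale
                else:
                    a = 100.0 - minor - p - b

                conc_kwargs = {}
                if config.total_vfa_conc_mean_sd is not None:
                    conc_mean, conc_sd = config.total_vfa_conc_mean_sd
                    total_conc = float(
                        np.clip(rng_cow.normal(conc_mean, conc_sd), 20.0, None)
                    )
                    conc_kwargs = {
                        "total_vfa_conc": total_conc,
                        "propionate_conc": p / 100.0 * total_conc,
                    }

                profile = VFAProfile(
                    acetate=a, propionate=p, butyrate=b, **conc_kwargs
                )
                signal = predict(truth, profile) + u + v
                my = signal + rng_cow.normal(0.0, math.sqrt(s2_cow))
                while my <= 0:  # methane yield is physically positive
                    my = signal + rng_cow.normal(0.0, math.sqrt(s2_cow))
                records.append(
                    CowRecord(
                        experiment_id=f"E{i + 1}",
                        treatment_id=f"T{j + 1}",
                        cow_id=f"C{k + 1}",
                        vfa=profile,
                        methane_yield=my,
                    )
                )
    return Dataset(
        records=records,
        provenance=(
            f"synthetic: form={truth.form.form_id} "
            f"coefficients={truth.coefficients.tolist()} "
            f"variance_components={tuple(config.variance_components)} "
            f"diet_shift_sd={config.diet_shift_sd} seed={seed}"
        ),
    )


def _simulated_my_sd(config: SimulationConfig, seeds: range) -> float:
    values = []
    for s in seeds:
        data = simulate_dataset(replace(config, seed=s))
        values.append([rec.methane_yield for rec in data])
    return float(np.std(np.concatenate(values), ddof=1))


def calibrate_spread(
    config: SimulationConfig,
    target_my_sd: float,
    n_replicates: int = 60,
    tol: float = 0.05,
    max_diet_shift_sd: float = 10.0,
) -> SimulationConfig:
    """Tune ``diet_shift_sd`` so the total methane-yield SD matches a target.

    Bisection on the simulated pooled SD over a fixed schedule of
    ``n_replicates`` seeds derived from ``config.seed``, so the
    calibration is deterministic.  The target must exceed the SD implied
    by the variance components alone (sqrt of their sum); if even a zero
    diet shift overshoots the target (the within-treatment VFA spread
    already generates too much signal), an :class:`UnattainableSpreadError`
    reports the closest achievable value.
    """
    floor = math.sqrt(sum(config.variance_components))
    if target_my_sd <= floor:
        raise UnattainableSpreadError(
            f"target SD {target_my_sd} not above the random-component floor "
            f"sqrt({sum(config.variance_components):.3g}) = {floor:.3f}",
            closest=floor,
        )
    seeds = range(int(config.seed) + 1_000_000, int(config.seed) + 1_000_000 + n_replicates)

    lo, hi = 0.0, max_diet_shift_sd
    sd_lo = _simulated_my_sd(replace(config, diet_shift_sd=lo), seeds)
    if sd_lo >= target_my_sd:
        raise UnattainableSpreadError(
            f"simulated SD {sd_lo:.3f} at zero diet shift already exceeds the "
            f"target {target_my_sd}",
            closest=sd_lo,
        )
    sd_hi = _simulated_my_sd(replace(config, diet_shift_sd=hi), seeds)
    if sd_hi <= target_my_sd:
        raise UnattainableSpreadError(
            f"simulated SD {sd_hi:.3f} at diet_shift_sd={hi} is below the "
            f"target {target_my_sd}",
            closest=sd_hi,
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _simulated_my_sd(replace(config, diet_shift_sd=mid), seeds) < target_my_sd:
            lo = mid
        else:
            hi = mid
    return replace(config, diet_shift_sd=round(0.5 * (lo + hi), 3))


FIXTURE_NAMES = ("noiseless_m3", "noiseless_m4", "shifted_bias", "tiny_2exp", "study_scale_seed42")


def make_fixture(name: str) -> Dataset:
    """Small deterministic datasets used throughout the test suite.

    - ``noiseless_m3``: varied profiles, zero random effects, methane
      yield exactly the published Model 3 equation.
    - ``noiseless_m4``: likewise for Model 4.
    - ``shifted_bias``: noiseless Model 4 data with +1 g/kg DMI added to
      every methane yield (pure mean-bias validation case).
    - ``tiny_2exp``: 2 experiments x 2 treatments x 3 cows = 12 records.
    - ``study_scale_seed42``: the default 215-record configuration at
      seed 42.
    """
    small = dict(
        n_experiments=2,
        treatments_per_experiment=(2, 2),
        cows_per_treatment=((5, 5), (5, 5)),
        variance_components=(0.0, 0.0, 0.0),
        total_vfa_conc_mean_sd=None,
        seed=7,
    )
    if name == "noiseless_m3":
        return simulate_dataset(SimulationConfig(true_form="M3", **small))
    if name == "noiseless_m4":
        return simulate_dataset(SimulationConfig(true_form="M4", **small))
    if name == "shifted_bias":
        base = simulate_dataset(SimulationConfig(true_form="M4", **small))
        return Dataset(
            records=[
                CowRecord(
                    experiment_id=r.experiment_id,
                    treatment_id=r.treatment_id,
                    cow_id=r.cow_id,
                    vfa=r.vfa,
                    methane_yield=r.methane_yield + 1.0,
                )
                for r in base
            ],
            provenance=base.provenance + " + constant 1.0 shift",
        )
    if name == "tiny_2exp":
        return simulate_dataset(
            SimulationConfig(
                n_experiments=2,
                treatments_per_experiment=(2, 2),
                cows_per_treatment=((3, 3), (3, 3)),
                total_vfa_conc_mean_sd=None,
                seed=11,
            )
        )
    if name == "study_scale_seed42":
        return simulate_dataset(SimulationConfig(seed=42))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
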