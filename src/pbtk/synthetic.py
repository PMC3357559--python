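"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all pure functions of (configuration, seed):

* noisy concentration-time profiles (multiplicative lognormal noise on a
  forward simulation) for parameter-recovery experiments;
* cumulative urinary-excretion series from a reduced first-order
  absorption -> body -> urine model, with a matching least-squares
  estimator of the absorption half-life;
* graded rat hepatotoxicity study sets in which severity is driven by a
  chosen kinetic metric (liver Cmax or whole-study liver AUC) computed
  through the rat model, so the dose-metric identification stage has a
  known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cases.coumarin import RatModel
from .core import SimulationResult, simulate


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


@dataclass
class SyntheticProfile:
    """Observed concentrations around a known simulated truth."""

    times_h: np.ndarray
    true_concentrations: np.ndarray
    observed: np.ndarray
    compartment: str
    cv: float
    seed: int
    result: SimulationResult = field(repr=False)


def gen_noisy_profile(
    model_config: dict,
    cv: float,
    seed: int,
    n_samples: int = 50,
    compartment: str = "blood",
) -> SyntheticProfile:
    """Simulate with the PBTK engine, then add i.i.d. multiplicative noise.

    ``model_config`` holds the built engine inputs: ``profile``,
    ``partitions``, ``pathways``, ``scenario`` and optionally
    ``solver_opts``.  Samples are drawn on an even subgrid.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    result = simulate(
        model_config["profile"],
        model_config["partitions"],
        model_config["pathways"],
        model_config["scenario"],
        model_config.get("solver_opts"),
    )
    idx = np.linspace(0, result.time.size - 1, n_samples).round().astype(int)
    truth = result.concentration(compartment)[idx]
    rng = np.random.default_rng(seed)
    observed = truth * _lognormal_factors(rng, cv, truth.size)
    return SyntheticProfile(
        times_h=result.time[idx],
        true_concentrations=truth,
        observed=observed,
        compartment=compartment,
        cv=cv,
        seed=seed,
        result=result,
    )


def cumulative_urinary_model(
    t: np.ndarray, ka: float, ke: float, total: float
) -> np.ndarray:
    """Cumulative urinary conjugate in the reduced chain model.

    First-order absorption (ka) into a body pool cleared first order
    (ke) entirely into urine:
    U(t) = total * [1 - (ke e^{-ka t} - ka e^{-ke t}) / (ke - ka)].
    """
    t = np.asarray(t, dtype=float)
    if abs(ka - ke) < 1e-9 * max(ka, ke):
        return total * (1.0 - np.exp(-ka * t) * (1.0 + ka * t))
    return total * (1.0 - (ke * np.exp(-ka * t) - ka * np.exp(-ke * t)) / (ke - ka))


def gen_urinary_series(
    absorption_half_life_h: float,
    elimination_rate_per_h: float,
    total_amount_ug: float,
    times_h: np.ndarray,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy cumulative urinary-excretion series from the reduced model."""
    ka = np.log(2.0) / absorption_half_life_h
    truth = cumulative_urinary_model(
        np.asarray(times_h, float), ka, elimination_rate_per_h, total_amount_ug
    )
    rng = np.random.default_rng(seed)
    observed = truth * _lognormal_factors(rng, cv, truth.size)
    return pd.DataFrame(
        {"time_h": times_h, "amount_ug": observed, "true_amount_ug": truth}
    )


def estimate_absorption_halflife(
    series: pd.DataFrame,
    elimination_fixture: dict,
    monotone_tol: float = 0.5,
) -> float:
    """Least-squares absorption half-life (h) from cumulative urinary data.

    Fits the first-order absorption rate of the reduced
    absorption -> elimination -> urine model, holding the elimination
    rate at the fixture value (``elimination_rate_per_h``) unless
    ``fit_elimination`` is set.  The series must be non-decreasing up to
    the multiplicative-noise tolerance.
    """
    t = np.asarray(series["time_h"], dtype=float)
    u = np.asarray(series["amount_ug"], dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 time points to fit the absorption rate")
    drops = np.diff(u)
    reference = np.maximum(u[:-1], 1e-12)
    if np.any(drops < -monotone_tol * reference):
        raise ValueError(
            "cumulative series decreases beyond the noise tolerance; "
            "not a valid excretion record"
        )
    ke = float(elimination_fixture["elimination_rate_per_h"])
    u_max = float(u.max())
    if elimination_fixture.get("fit_elimination"):
        popt, _ = curve_fit(
            cumulative_urinary_model,
            t,
            u,
            p0=(1.0, ke, u_max),
            bounds=([1e-4, 1e-4, 1e-9], [1e3, 1e3, 10 * u_max + 1e-9]),
            maxfev=20000,
        )
        ka = popt[0]
    else:
        popt, _ = curve_fit(
            lambda tt, ka, total: cumulative_urinary_model(tt, ka, ke, total),
            t,
            u,
            p0=(1.0, u_max),
            bounds=([1e-4, 1e-9], [1e3, 10 * u_max + 1e-9]),
            maxfev=20000,
        )
        ka = popt[0]
    return float(np.log(2.0) / ka)


@dataclass
class SyntheticToxStudySet:
    """Ground-truth-labelled rat hepatotoxicity study set."""

    records: pd.DataFrame  # study_id, dose, duration, administration, grade
    mechanism: str  # cmax_driven | auc_driven
    grade_threshold: float
    grade_slope: float
    noise_p: float
    seed: int
    true_metric_values: np.ndarray = field(repr=False)


def gen_tox_study_set(
    mechanism: str,
    n_studies: int = 11,
    groups_per_study: tuple[int, int] = (2, 4),
    dose_range: tuple[float, float] = (2.3, 535.0),
    duration_range: tuple[float, float] = (4.0, 104.0),
    noise_p: float = 0.1,
    seed: int = 0,
    n_records: int = 31,
    rat_model: RatModel | None = None,
    grade_slope: float | None = None,
    grade_threshold: float | None = None,
) -> SyntheticToxStudySet:
    """Sample a study design and grade severity from a driving metric.

    Designs are sampled log-uniformly over the dose and duration ranges
    (defaults match the span of chronic oral coumarin studies:
    2.3-535 mg/kg/day, 4-104 weeks).  Each study carries one duration
    and administration mode; its dose groups are sorted ascending.  The
    driving metric is computed through the rat model
    (``cmax_driven``: daily liver peak; ``auc_driven``: whole-study
    liver AUC) and graded as

        grade = clamp(floor(a * log10(metric / theta)), 0, 4)

    with slope ``a`` and threshold ``theta`` defaulting to the values
    that spread the sampled metric range evenly over the five grades;
    grades are then flipped by +/-1 with probability ``noise_p``.
    """
    if mechanism not in ("cmax_driven", "auc_driven"):
        raise ValueError(f"unknown grading mechanism {mechanism!r}")
    lo, hi = dose_range
    if not 0 < lo < hi <= 1000.0:
        raise ValueError("dose range must satisfy 0 < low < high <= 1000 mg/kg/day")
    d_lo, d_hi = duration_range
    if not 0 < d_lo < d_hi:
        raise ValueError("invalid duration range")
    g_lo, g_hi = groups_per_study
    if not (n_studies * g_lo <= n_records <= n_studies * g_hi):
        raise ValueError(
            f"{n_records} records infeasible for {n_studies} studies with "
            f"{g_lo}-{g_hi} groups each"
        )

    rng = np.random.default_rng(seed)
    counts = np.full(n_studies, g_lo)
    while counts.sum() < n_records:
        candidates = np.flatnonzero(counts < g_hi)
        counts[rng.choice(candidates)] += 1

    rows = []
    for s in range(n_studies):
        duration = float(
            np.exp(rng.uniform(np.log(d_lo), np.log(d_hi)))
        )
        administration = rng.choice(["dietary", "gavage"])
        doses = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=counts[s])))
        for dose in doses:
            rows.append(
                {
                    "study_id": f"SYN{s + 1:02d}",
                    "dose_mg_per_kg_day": float(dose),
                    "duration_weeks": duration,
                    "administration": str(administration),
                }
            )
    records = pd.DataFrame(rows)

    model = rat_model or RatModel()
    values = []
    for row in records.itertuples():
        cmax_hep, daily_auc = model.daily_metrics(
            row.dose_mg_per_kg_day, row.administration
        )
        values.append(
            cmax_hep
            if mechanism == "cmax_driven"
            else daily_auc * row.duration_weeks * 7.0
        )
    values = np.asarray(values)

    theta = grade_threshold if grade_threshold is not None else float(values.min())
    if grade_slope is not None:
        a = grade_slope
    else:
        decades = np.log10(values.max() / theta)
        if decades <= 0:
            raise ValueError("degenerate metric range; cannot auto-scale grades")
        a = 5.0 * (1.0 - 1e-9) / decades
    grades = np.clip(
        np.floor(a * np.log10(values / theta)).astype(int), 0, 4
    )
    flips = rng.random(grades.size) < noise_p
    signs = rng.choice([-1, 1], size=grades.size)
    grades = np.clip(grades + flips * signs, 0, 4)
    records["grade"] = grades

    return SyntheticToxStudySet(
        records=records,
        mechanism=mechanism,
        grade_threshold=theta,
        grade_slope=float(a),
        noise_p=noise_p,
        seed=seed,
        true_metric_values=values,
    )
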