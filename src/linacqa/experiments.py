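"""Monte Carlo engine: error distributions of reconstructed geometric parameters.

Fixing the test plan, the two phantom modules and the noise level, the
engine repeats simulate -> reconstruct many times and summarizes the
dispersion (standard deviation with a chi-square confidence interval) of
each error metric:

====== ======================================================== =======
metric definition                                               units
====== ======================================================== =======
alpha  estimated minus nominal collimator-axis-vs-vertical      deg
       angle, one value per gantry angle
theta  angle between estimated and nominal gantry rotation axis deg
omega  field corner angles minus 90, four per image             deg
L      field edge lengths minus nominal, four per image         cm
s      components of the estimated isocenter, three per         cm
       replicate
l      distance of the estimated isocenter from the origin      cm
dsad   estimated minus nominal SAD, one per image               cm
dsdd   estimated minus nominal SDD, one per image               cm
====== ======================================================== =======

The probabilistic test machinery (empirical tail probabilities and tolerance
thresholds) lives here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ReconstructionError, VisibilityError
from .geometry import angle_between, wrap_angle_deg
from .phantom import PhantomModule, validate_configuration
from .plan import TestPlan
from .reconstruct import ReconstructedGeometry, reconstruct_plan
from .simulate import nominal_state, simulate_plan

logger = logging.getLogger(__name__)

METRICS = ("alpha", "theta", "omega", "L", "s", "l", "dsad", "dsdd")

METRIC_UNITS = {
    "alpha": "deg", "theta": "deg", "omega": "deg", "L": "cm",
    "s": "cm", "l": "cm", "dsad": "cm", "dsdd": "cm",
}

#: Fraction of failed replicates above which an experiment aborts.
MAX_FAILURE_FRACTION = 0.01


@dataclass(frozen=True)
class ExperimentConfig:
    plan: TestPlan
    table: PhantomModule
    collimator: PhantomModule
    n_replicates: int
    seed: int = 0
    include_sources: bool = True
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ConfigurationError(f"unknown metrics: {sorted(unknown)}")


@dataclass(frozen=True)
class ErrorSample:
    """Per-replicate deviations of every reconstructed quantity from nominal."""

    replicate: int
    alpha: np.ndarray  # (n_gantry,) deg
    theta: float  # deg, >= 0
    omega: np.ndarray  # (n_images, 4) deg
    L: np.ndarray  # (n_images, 4) cm
    s: np.ndarray  # (3,) cm
    l: float  # cm, >= 0
    dsad: np.ndarray  # (n_images,) cm
    dsdd: np.ndarray  # (n_images,) cm

    def values(self, metric: str) -> np.ndarray:
        v = getattr(self, metric)
        return np.atleast_1d(np.asarray(v, dtype=float)).ravel()


def compute_error_metrics(
    recon: ReconstructedGeometry, plan: TestPlan, replicate: int = 0
) -> ErrorSample:
    """Differences between reconstructed and nominal geometry for one replicate."""
    machine = plan.machine
    alpha = wrap_angle_deg(
        np.asarray(recon.vertical_angles_signed) - np.asarray(recon.gantry_angles)
    )
    theta = angle_between(recon.gantry_axis, np.array([0.0, 1.0, 0.0]))
    omega = np.array([f.corner_angles - 90.0 for f in recon.fields])
    # edges AB and CD run along the first field axis, BC and DA along the second
    fu, fv = machine.field_size
    nominal_edges = np.array([fu, fv, fu, fv])
    L = np.array([f.edge_lengths - nominal_edges for f in recon.fields])
    s = np.asarray(recon.isocenter, dtype=float)
    return ErrorSample(
        replicate=replicate,
        alpha=alpha,
        theta=float(theta),
        omega=omega,
        L=L,
        s=s,
        l=float(np.linalg.norm(s)),
        dsad=recon.image_sad - machine.sad,
        dsdd=recon.image_sdd - machine.sdd,
    )


def summarize_sd(samples: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample standard deviation with a chi-square confidence interval."""
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ConfigurationError("need at least 2 samples to estimate an SD")
    sd = float(np.std(x, ddof=1))
    a = 1.0 - confidence
    lo = sd * np.sqrt((n - 1) / sps.chi2.ppf(1.0 - a / 2.0, n - 1))
    hi = sd * np.sqrt((n - 1) / sps.chi2.ppf(a / 2.0, n - 1))
    return sd, float(lo), float(hi)


@dataclass
class SummaryTable:
    """Pooled SD (and CI) of each metric for one experiment configuration."""

    rows: pd.DataFrame
    n_replicates: int
    n_failures: int
    sigma_mm: float

    def sd(self, metric: str) -> float:
        return float(self.rows.loc[self.rows["metric"] == metric, "sd"].iloc[0])

    def to_csv(self) -> str:
        return self.rows.to_csv(index=False)


def _summary_from_samples(
    samples: list[ErrorSample], metrics, sigma_mm: float, n_failures: int
) -> SummaryTable:
    rows = []
    for m in metrics:
        pooled = np.concatenate([s.values(m) for s in samples])
        sd, lo, hi = summarize_sd(pooled)
        rows.append(
            {"metric": m, "unit": METRIC_UNITS[m], "sd": sd, "ci95_low": lo,
             "ci95_high": hi, "n_samples": pooled.size}
        )
    return SummaryTable(
        rows=pd.DataFrame(rows),
        n_replicates=len(samples),
        n_failures=n_failures,
        sigma_mm=sigma_mm,
    )


def run_experiment(config: ExperimentConfig) -> tuple[list[ErrorSample], SummaryTable]:
    """Monte Carlo over replicates: simulate, reconstruct, collect error metrics.

    The configuration is validated once up front: visibility violations abort;
    projected-disk overlaps are logged as warnings (marker identification
    gates on nominal predicted positions, so isolated overlaps do not corrupt
    coordinate-level simulation).  Replicates whose reconstruction fails are
    excluded and counted; more than ``MAX_FAILURE_FRACTION`` failing aborts.
    """
    plan = config.plan
    report = validate_configuration(config.table, config.collimator, plan)
    if report.outside:
        raise VisibilityError(f"invalid configuration:\n{report}")
    if report.overlaps:
        logger.warning(
            "%d projected-disk overlap(s) across the plan (coordinate statistics unaffected)",
            len(report.overlaps),
        )

    machine = plan.machine
    corner_cache: dict[tuple[float, float], np.ndarray] = {}

    def nominal_corners(theta: float, psi: float) -> np.ndarray:
        key = (theta, psi)
        if key not in corner_cache:
            corner_cache[key] = nominal_state(theta, psi, machine).field_corners
        return corner_cache[key]

    samples: list[ErrorSample] = []
    failures: list[tuple[int, str]] = []
    max_failures = max(1, int(MAX_FAILURE_FRACTION * config.n_replicates))
    for rep in range(config.n_replicates):
        records = simulate_plan(
            plan, config.table, config.collimator,
            seed=config.seed, replicate=rep, check_visibility=False, keep_truth=False,
        )
        try:
            recon = reconstruct_plan(
                records, config.table, config.collimator, machine=machine,
                include_sources=config.include_sources, nominal_corner_fn=nominal_corners,
            )
        except ReconstructionError as exc:
            failures.append((rep, str(exc)))
            logger.debug("replicate %d failed: %s", rep, exc)
            if len(failures) > max_failures:
                raise ReconstructionError(
                    f"{len(failures)}/{rep + 1} replicates failed; first: {failures[0]}"
                ) from exc
            continue
        samples.append(compute_error_metrics(recon, plan, replicate=rep))
        if (rep + 1) % 100 == 0:
            logger.info("replicate %d/%d done", rep + 1, config.n_replicates)
    summary = _summary_from_samples(samples, config.metrics, plan.sigma_mm, len(failures))
    return samples, summary


def samples_to_frame(samples: list[ErrorSample], metrics=METRICS) -> pd.DataFrame:
    """Long-format frame of all raw error samples (one row per scalar value)."""
    rows = []
    for s in samples:
        for m in metrics:
            for v in s.values(m):
                rows.append({"replicate": s.replicate, "metric": m, "value": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic thresholds
# ---------------------------------------------------------------------------


def tail_probability(samples: np.ndarray, nominal: float, delta_m: float) -> float:
    """Empirical probability that |Q_M - Q_N| >= delta_M under the null model.

    ``samples`` are measured values of the parameter in a correctly tuned
    device (e.g. from the Monte Carlo); a small tail probability for an
    observed difference flags a failed geometric test.
    """
    x = np.abs(np.asarray(samples, dtype=float).ravel() - nominal)
    if x.size == 0:
        raise ConfigurationError("no samples")
    if x.size < 100:
        logger.warning("tail probability from only %d samples is unreliable", x.size)
    return float(np.mean(x >= delta_m))


def tolerance_threshold(samples: np.ndarray, nominal: float, pr_th: float) -> float:
    """Tolerated difference Delta_TH: the (1 - Pr_TH) quantile of |Q_M - Q_N|.

    Deviations larger than the returned threshold occur with probability at
    most ``pr_th`` in a correctly tuned device.
    """
    if not 0.0 < pr_th < 1.0:
        raise ConfigurationError("Pr_TH must be in (0, 1)")
    x = np.abs(np.asarray(samples, dtype=float).ravel() - nominal)
    if x.size == 0:
        raise ConfigurationError("no samples")
    if x.size < 100:
        logger.warning("threshold from only %d samples is unreliable", x.size)
    return float(np.quantile(x, 1.0 - pr_th))
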