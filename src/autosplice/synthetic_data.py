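"""Synthetic data generators for every input class the pipeline consumes.

Four generators, each emitting its ground truth alongside the data so every
downstream stage is testable without external downloads:

* single-cell fluorescence traces (delayed rise-to-plateau with per-cell
  variability in induction strength and onset delay, additive measurement
  noise, background floor);
* condition-averaged curves for the four (circuit x induction) conditions,
  the inputs to Bayesian parameter fitting;
* population-snapshot intensity vectors (lognormal signal on a background
  floor, flow-cytometry-like);
* binding-record / TPM tables with a planted factor-load correlation.

Per-cell heterogeneity enters only through the ectopic production rate
(lognormal, median-preserving) and the onset delay (shifted gamma), the two
sources visible in the movie data; all other parameters are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    Circuit,
    Induction,
    ModelParameters,
    Trajectory,
    simulate_fast,
)

__all__ = [
    "DelaySpec",
    "CellPopulationSpec",
    "SyntheticTargetTableSpec",
    "CurveSet",
    "generate_single_cell_traces",
    "generate_average_curves",
    "generate_snapshot",
    "generate_target_table",
]


class ConfigurationError(ValueError):
    """A generator spec is invalid."""


@dataclass(frozen=True)
class DelaySpec:
    """Distribution of the per-cell onset delay t0 (hours).

    ``kind='shifted_gamma'`` draws ``shift + Gamma(shape, scale)``;
    ``kind='fixed'`` returns ``shift`` for every cell.  When ``shift`` is
    None it defaults to the condition's mean delay (fixed kind) or 60% of it
    (shifted_gamma), with shape/scale set so the mean equals the condition
    delay.
    """

    kind: str = "shifted_gamma"
    shape: float = 3.0
    scale: float | None = None
    shift: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("shifted_gamma", "fixed"):
            raise ConfigurationError(f"unknown delay distribution {self.kind!r}")
        if self.shape <= 0:
            raise ConfigurationError("gamma shape must be > 0")
        if self.scale is not None and self.scale < 0:
            raise ConfigurationError("gamma scale must be >= 0")
        if self.shift is not None and self.shift < 0:
            raise ConfigurationError("shift must be >= 0")

    def sample(self, rng: np.random.Generator, n: int,
               condition_delay: float) -> np.ndarray:
        if self.kind == "fixed":
            shift = condition_delay if self.shift is None else self.shift
            return np.full(n, shift)
        shift = 0.6 * condition_delay if self.shift is None else self.shift
        scale = self.scale
        if scale is None:
            scale = max(condition_delay - shift, 0.0) / self.shape
        if scale == 0.0:
            return np.full(n, shift)
        return shift + rng.gamma(self.shape, scale, size=n)


@dataclass(frozen=True)
class CellPopulationSpec:
    """Study conditions for a synthetic movie: ~200 cells imaged every 10 min
    over 40 h, with lognormal induction-strength variability (CV 0.3)."""

    n_cells: int = 200
    params_base: ModelParameters = field(default_factory=ModelParameters)
    cv_alpha: float = 0.3
    delay_dist: DelaySpec = field(default_factory=DelaySpec)
    noise_sd: float = 15.0
    cadence: float = 1.0 / 6.0
    horizon: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.cadence <= 0:
            raise ConfigurationError("cadence must be > 0")
        if self.horizon <= self.cadence:
            raise ConfigurationError("horizon must exceed cadence")
        if self.cv_alpha < 0 or self.noise_sd < 0:
            raise ConfigurationError("cv_alpha and noise_sd must be >= 0")

    def times(self) -> np.ndarray:
        n = int(round(self.horizon / self.cadence))
        return np.linspace(0.0, n * self.cadence, n + 1)


def _lognormal_around_median(rng: np.random.Generator, median: float,
                             cv: float, n: int) -> np.ndarray:
    """Lognormal draws with the given median and coefficient of variation."""
    if cv == 0.0 or median == 0.0:
        return np.full(n, median)
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def generate_single_cell_traces(
    spec: CellPopulationSpec, circuit: Circuit | str, induction: Induction | str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a synthetic cell population for one condition.

    Returns ``(traces, truth)``: a long-format table (cell_id, time_h,
    intensity) and the per-cell ground truth (cell_id, alpha_ec, t_delay).
    """
    circuit = Circuit(circuit)
    induction = Induction(induction)
    rng = np.random.default_rng(spec.seed)
    base = spec.params_base
    times = spec.times()

    alpha_med = base.alpha_ec(induction)
    cond_delay = base.t_delay(induction)
    alphas = _lognormal_around_median(rng, alpha_med, spec.cv_alpha, spec.n_cells)
    delays = spec.delay_dist.sample(rng, spec.n_cells, cond_delay)

    frames = []
    for i, (a, d) in enumerate(zip(alphas, delays)):
        if induction is Induction.LOW:
            pcell = base.replace(alpha_ec_lo=float(a), t_delay_lo=float(d))
        else:
            pcell = base.replace(alpha_ec_hi=float(a), t_delay_hi=float(d))
        traj = simulate_fast(pcell, circuit, induction, times)
        noisy = traj.observable + rng.normal(0.0, spec.noise_sd, size=len(times))
        noisy = np.maximum(noisy, base.bg)
        frames.append(pd.DataFrame({
            "cell_id": i, "time_h": times, "intensity": noisy,
        }))
    traces = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({
        "cell_id": np.arange(spec.n_cells),
        "alpha_ec": alphas,
        "t_delay": delays,
    })
    return traces, truth


@dataclass(frozen=True)
class CurveSet:
    """Condition-averaged observed curves on a shared time grid."""

    times: np.ndarray
    curves: dict  # (Circuit, Induction) -> np.ndarray

    def conditions(self) -> list[tuple[Circuit, Induction]]:
        return list(self.curves)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for (c, i), v in self.curves.items():
            df[f"{c.value}_{i.value}"] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CurveSet":
        times = df["time_h"].to_numpy(dtype=float)
        curves = {}
        for col in df.columns:
            if col == "time_h":
                continue
            circ, ind = col.rsplit("_", 1)
            curves[(Circuit(circ), Induction(ind))] = df[col].to_numpy(dtype=float)
        return cls(times=times, curves=curves)


def generate_average_curves(
    params: ModelParameters | None = None, *,
    circuits: Sequence[Circuit | str] = (Circuit.NO_FEEDBACK, Circuit.FEEDBACK),
    inductions: Sequence[Induction | str] = (Induction.LOW, Induction.HIGH),
    times: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CurveSet, ModelParameters]:
    """Simulate the condition-averaged curves from one shared parameter set.

    Conditions differ only through the production rate and delay; Gaussian
    noise of sd ``params.sigma_obs`` is added to each curve.  Returns the
    noisy curve set and the ground-truth parameters.
    """
    if params is None:
        params = ModelParameters()
    rng = np.random.default_rng(seed)
    if times is None:
        n = int(round(40.0 / (1.0 / 6.0)))
        times = np.linspace(0.0, n / 6.0, n + 1)
    curves = {}
    for c in circuits:
        for i in inductions:
            c_, i_ = Circuit(c), Induction(i)
            traj = simulate_fast(params, c_, i_, times)
            # measurement noise is not floored: the background floor applies
            # to the underlying observable, not to noise excursions around it
            curves[(c_, i_)] = traj.observable + rng.normal(
                0.0, params.sigma_obs, len(times))
    return CurveSet(times=np.asarray(times, float), curves=curves), params


def generate_snapshot(n: int, log_mean: float = 3.0, log_sd: float = 0.3,
                      bg_level: float = 1.0, bg_sd: float = 0.3,
                      frac_background: float = 0.1,
                      seed: int = 0) -> np.ndarray:
    """Flow-cytometry-like intensity vector: a lognormal signal component
    riding on a Gaussian background floor, mixed with pure-background cells.
    """
    if not 0.0 <= frac_background <= 1.0:
        raise ConfigurationError("frac_background must be in [0, 1]")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    is_bg = rng.random(n) < frac_background
    bg = rng.normal(bg_level, bg_sd, size=n)
    signal = np.exp(rng.normal(log_mean, log_sd, size=n))
    out = np.where(is_bg, bg, signal + bg)
    return out


@dataclass(frozen=True)
class SyntheticTargetTableSpec:
    """Fixture spec for the target-load correlation procedure.

    The genes with the highest binding-record counts are the planted targets;
    their summed TPM across tissues is constructed so that, in log1p space,
    its correlation with the factor TPM equals ``rho_true`` (exactly ±1 when
    ``rho_true`` is ±1).
    """

    n_genes: int = 500
    n_tissues: int = 53
    records_dist: tuple = ("pareto", 2.0, 10.0)  # (name, shape, scale)
    rho_true: float = 0.8
    top_frac: float = 0.02
    factor_log_mean: float = 4.0
    factor_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.n_tissues < 3:
            raise ConfigurationError("n_tissues must be >= 3")
        if abs(self.rho_true) > 1:
            raise ConfigurationError("|rho_true| must be <= 1")
        if not 0 < self.top_frac < 1:
            raise ConfigurationError("top_frac must be in (0, 1)")


def _sample_records(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    name = dist[0]
    if name == "pareto":
        shape, scale = dist[1], dist[2]
        return np.floor(scale * (1.0 + rng.pareto(shape, size=n))).astype(int)
    if name == "poisson":
        return rng.poisson(dist[1], size=n)
    raise ConfigurationError(f"unknown records distribution {name!r}")


def generate_target_table(spec: SyntheticTargetTableSpec):
    """Build a (records, TPM) table pair with a planted factor-load correlation.

    Returns ``(table, truth)`` where ``table`` is a
    :class:`autosplice.target_load.TargetTable` and ``truth`` records the
    planted target genes and correlation.
    """
    from .target_load import TargetTable

    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    factor = "FACTOR"

    records = _sample_records(rng, spec.records_dist, spec.n_genes)
    n_top = max(1, int(np.ceil(spec.top_frac * spec.n_genes)))
    order = np.argsort(-records, kind="stable")
    planted_idx = order[:n_top]
    # make the planted genes strictly the record leaders
    floor = records[order[n_top - 1]] if n_top <= len(order) else 0
    records = np.minimum(records, max(floor - 1, 0))
    records[planted_idx] = np.sort(
        rng.integers(floor + 10, floor + 1000, size=n_top))[::-1]

    # factor TPM across tissues, in log1p space; the load is constructed so
    # its SAMPLE correlation with the factor equals rho_true exactly (the
    # noise direction is residualized against the factor before mixing)
    g_factor = rng.normal(spec.factor_log_mean, spec.factor_log_sd,
                          size=spec.n_tissues)
    z = rng.normal(0.0, 1.0, size=spec.n_tissues)
    gf_std = (g_factor - g_factor.mean()) / g_factor.std()
    z = z - z.mean() - (z @ gf_std) / (gf_std @ gf_std) * gf_std
    z_std = z / z.std() if z.std() > 0 else z
    rho = spec.rho_true
    g_load = spec.factor_log_mean + 1.5 + spec.factor_log_sd * (
        rho * gf_std + np.sqrt(max(1.0 - rho * rho, 0.0)) * z_std)
    load = np.expm1(g_load)  # per-tissue summed TPM of the planted targets

    weights = rng.dirichlet(np.full(n_top, 5.0))
    tpm = np.empty((spec.n_genes, spec.n_tissues))
    # background genes: iid lognormal expression
    tpm[:] = np.exp(rng.normal(1.0, 1.0, size=tpm.shape))
    tpm[planted_idx, :] = np.outer(weights, load)

    tpm_df = pd.DataFrame(tpm, index=genes,
                          columns=[f"tissue{t:02d}" for t in range(spec.n_tissues)])
    tpm_df.loc[factor] = np.expm1(g_factor)
    records_s = pd.Series(records, index=genes, name="binding_site_records")
    records_s.loc[factor] = 0
    table = TargetTable(records=records_s, tpm=tpm_df, factor_gene=factor)
    truth = {
        "planted_genes": [genes[i] for i in planted_idx],
        "rho_true": rho,
        "load": load,
    }
    return table, truth
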