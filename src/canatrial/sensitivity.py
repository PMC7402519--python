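"""Population-of-models sensitivity analysis and one-at-a-time scaling scans.

A population of model variants is drawn by multiplying each of the seven
HF-remodelled parameters (G_Ca, G_to, G_Ks, J_up(max), K_up, J_rel(max),
[Csqn]_max) by independent log-normal factors; each variant is paced to
quasi-steady state and its APD90, CaT amplitude and SR Ca2+ content are
regressed (ordinary least squares on standardized log-log variables) on the
log scale factors.  The resulting coefficient matrix quantifies the relative
contribution of every parameter to every output; the one-at-a-time scan
instead maps how graded scaling of a single parameter moves the alternans
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from canatrial import alternans as alt
from canatrial.cell_model import (
    CellParameters, NumericalInstabilityError, default_stimulus,
)
from canatrial.pacing import dynamic_pacing_scan, pace_fixed_pcl
from canatrial.remodelling import REMODELLED_PARAMS, RemodellingConfig

__all__ = ["PopulationSpec", "SensitivityResult", "generate_population",
           "simulate_population_outputs", "regress_sensitivities", "oat_scan",
           "OUTPUT_NAMES"]

OUTPUT_NAMES = ("apd90", "cat_amplitude", "sr_content")
DEFAULT_PARAMS = tuple(REMODELLED_PARAMS)


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a population of model variants."""

    n_variants: int = 300
    varied: tuple = DEFAULT_PARAMS
    sigma: float = 0.1   # SD of the log scale factors
    seed: int = 0
    baseline: str = "control"

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("population needs at least 2 variants")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        unknown = set(self.varied) - set(REMODELLED_PARAMS)
        if unknown:
            raise ValueError(f"unknown varied parameters: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"n_variants": self.n_variants, "varied": list(self.varied),
                "sigma": self.sigma, "seed": self.seed,
                "baseline": self.baseline}


@dataclass
class SensitivityResult:
    """Standardized regression coefficients (parameters x outputs)."""

    coefficients: pd.DataFrame  # index: parameter, columns: outputs
    r_squared: pd.Series
    spec: PopulationSpec

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "r_squared": self.r_squared.to_dict(),
            "spec": self.spec.to_dict(),
        }


def generate_population(base_params: CellParameters, spec: PopulationSpec):
    """Draw the variant parameter sets and the n x p log-scale matrix.

    Each variant multiplies each varied parameter by an independent
    log-normal factor exp(N(0, sigma^2)); fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    log_scales = rng.normal(0.0, spec.sigma,
                            size=(spec.n_variants, len(spec.varied)))
    factors = np.exp(log_scales)
    variants = []
    for row in factors:
        kw = {REMODELLED_PARAMS[name]: getattr(base_params,
                                               REMODELLED_PARAMS[name]) * f
              for name, f in zip(spec.varied, row)}
        variants.append(base_params.replace(**kw))
    return variants, pd.DataFrame(log_scales, columns=list(spec.varied))


def simulate_population_outputs(variants, pcl: float = 1000.0,
                                n_beats: int = 100,
                                stimulus=None) -> pd.DataFrame:
    """Quasi-steady APD90, CaT amplitude and NSR content for each variant.

    Outputs are measured on the final beat after ``n_beats`` at the given
    PCL.  Variants whose simulation fails yield NaN rows (dropped by the
    regression).  The stimulus is resolved once on the first variant and
    reused so all variants see an identical drive.
    """
    rows = []
    stim = stimulus
    for params in variants:
        if stim is None:
            stim = default_stimulus(params)
        try:
            tr, _ = pace_fixed_pcl(params, pcl, n_beats, record_last=2,
                                   stimulus=stim)
            b = tr.biomarkers().iloc[-1]
            rows.append({"apd90": b["apd90_ms"],
                         "cat_amplitude": b["cat_amp_nM"],
                         "sr_content": b["nsr_mM"]})
        except NumericalInstabilityError:
            rows.append({k: np.nan for k in OUTPUT_NAMES})
    return pd.DataFrame(rows)


def regress_sensitivities(log_scales: pd.DataFrame, outputs: pd.DataFrame,
                          spec: PopulationSpec | None = None
                          ) -> SensitivityResult:
    """OLS of standardized log outputs on standardized log scale factors.

    Rows with non-finite or non-positive outputs are dropped.  A
    rank-deficient design raises, naming the collinear columns.
    """
    X = log_scales.to_numpy(dtype=float)
    Y = outputs.to_numpy(dtype=float)
    ok = np.all(np.isfinite(Y), axis=1) & np.all(Y > 0, axis=1)
    X, Y = X[ok], np.log(Y[ok])
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few valid variants for regression")

    def standardize(M):
        sd = M.std(axis=0, ddof=1)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (M - M.mean(axis=0)) / sd_safe, sd

    Xs, x_sd = standardize(X)
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        # identify offending columns by pairwise correlation
        c = np.corrcoef(Xs, rowvar=False)
        bad = [(log_scales.columns[i], log_scales.columns[j])
               for i in range(c.shape[0]) for j in range(i + 1, c.shape[0])
               if abs(c[i, j]) > 0.999]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Ys, y_sd = standardize(Y)
    # zero-variance outputs get zero coefficients by construction
    Ys[:, y_sd == 0] = 0.0
    beta, _, _, _ = np.linalg.lstsq(Xs, Ys, rcond=None)
    resid = Ys - Xs @ beta
    tot = (Ys ** 2).sum(axis=0)
    r2 = np.where(tot > 0, 1.0 - (resid ** 2).sum(axis=0) / np.where(tot > 0, tot, 1.0), 1.0)
    coeff = pd.DataFrame(beta, index=list(log_scales.columns),
                         columns=list(outputs.columns))
    return SensitivityResult(
        coefficients=coeff,
        r_squared=pd.Series(r2, index=list(outputs.columns)),
        spec=spec if spec is not None else PopulationSpec(),
    )


def oat_scan(base_params: CellParameters, param_name: str, scale_list,
             pcl_ladder, beats_per_pcl: int = 40,
             base_config: RemodellingConfig | None = None) -> pd.DataFrame:
    """Alternans window as one parameter is scaled through ``scale_list``.

    ``base_config`` supplies the background remodelling (e.g. the full HF
    phenotype); the named parameter's entry is overridden by each scale in
    turn.  Per-scale failures are recorded (pattern ``error``), the scan
    continues.  Returns columns ``scale, onset_pcl_ms, offset_pcl_ms,
    max_magnitude, status``.
    """
    from canatrial.remodelling import apply_remodelling
    if param_name not in REMODELLED_PARAMS:
        raise ValueError(f"unknown parameter: {param_name}")
    cfg0 = base_config if base_config is not None else RemodellingConfig()
    rows = []
    for scale in scale_list:
        if not scale > 0:
            raise ValueError("scales must be positive")
        cfg = cfg0.with_scale(param_name, float(scale))
        params = apply_remodelling(base_params, cfg)
        try:
            curve, _ = dynamic_pacing_scan(params, pcl_ladder,
                                           beats_per_pcl=beats_per_pcl)
            win = alt.alternans_window(curve)
            rows.append({
                "scale": float(scale),
                "onset_pcl_ms": win.onset_pcl if win else np.nan,
                "offset_pcl_ms": win.offset_pcl if win else np.nan,
                "max_magnitude": win.max_magnitude if win else np.nan,
                "status": "alternans" if win else "none",
            })
        except NumericalInstabilityError as err:
            rows.append({"scale": float(scale), "onset_pcl_ms": np.nan,
                         "offset_pcl_ms": np.nan, "max_magnitude": np.nan,
                         "status": f"error: {err.variable}"})
    return pd.DataFrame(rows)
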