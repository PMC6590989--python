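"""Hill-equation dose-response fitting and condition comparison.

Per-cell peak calcium responses ΔCa²⁺ to an agonist at concentration ``c``
are modelled by the Hill equation

    ΔCa²⁺(c) = Max · c^H / (c^H + EC50^H)

with ``Max`` the saturating response (µM Ca²⁺), ``EC50`` the half-effective
agonist concentration (µM) and ``H`` (H_S) the Hill coefficient.  Fits pool
all cells of one condition into a single nonlinear least-squares problem (the
alternative — fitting per-concentration means — is available via
``aggregate="mean"``).  Conditions are compared by the EC50 fold change and
Max ratio with percentile-bootstrap intervals obtained by resampling cells
within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "CellResponse",
    "DoseResponseFit",
    "ConditionComparison",
    "predict_hill",
    "fit_hill",
    "compare_conditions",
    "classify_mcd_sensitivity",
    "responses_to_frame",
    "read_responses",
]

HS_BOUNDS = (0.3, 10.0)


@dataclass(frozen=True)
class CellResponse:
    """One cell's baseline-corrected peak ΔCa²⁺ at one agonist concentration."""

    concentration: float  # µM agonist
    delta_ca: float  # µM Ca²⁺
    condition: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if not np.isfinite(self.delta_ca):
            raise ValueError("delta_ca must be finite")


@dataclass(frozen=True)
class DoseResponseFit:
    max_response: float
    ec50: float
    hill_coefficient: float
    max_stderr: float | None
    ec50_stderr: float | None
    hill_stderr: float | None
    residual_ss: float
    n_cells: int
    converged: bool
    message: str = ""

    def predict(self, concentration) -> np.ndarray:
        return predict_hill(
            self.max_response, self.ec50, self.hill_coefficient, concentration
        )


def predict_hill(max_response, ec50, hill_coefficient, concentration):
    """Evaluate Max · c^H / (c^H + EC50^H), stably in log space.

    Written as Max / (1 + exp(H · (log EC50 − log c))) so extreme
    concentrations neither overflow nor lose the asymptotes.
    """
    max_response = np.asarray(max_response, dtype=float)
    ec50 = np.asarray(ec50, dtype=float)
    hill_coefficient = np.asarray(hill_coefficient, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if np.any(max_response <= 0) or np.any(ec50 <= 0) or np.any(hill_coefficient <= 0):
        raise ValueError("Max, EC50 and the Hill coefficient must be positive")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        logit = hill_coefficient * (np.log(ec50) - np.log(c))
        out = max_response / (1.0 + np.exp(logit))
    out = np.where(c == 0, 0.0, out)
    return out if out.ndim else float(out)


def _hill_model_logp(log_max, log_ec50, log_hs, concentration):
    return predict_hill(np.exp(log_max), np.exp(log_ec50), np.exp(log_hs), concentration)


def fit_hill(
    responses: list[CellResponse] | pd.DataFrame,
    aggregate: str = "pooled",
) -> DoseResponseFit:
    """Fit the Hill equation to a set of cell responses.

    Parameters are log-transformed so positivity is structural; the Hill
    coefficient is additionally bounded to [0.3, 10].  Initial values: Max at
    the largest per-concentration mean response, EC50 at the concentration
    whose mean response first crosses half of that, H = 1.

    ``aggregate="pooled"`` fits all cells jointly (default);
    ``aggregate="mean"`` fits the per-concentration mean responses.
    Non-convergence is flagged on the returned fit, never silent.
    """
    df = responses_to_frame(responses)
    if df.empty:
        raise ValueError("no responses to fit")
    if aggregate not in ("pooled", "mean"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    means = df.groupby("concentration")["delta_ca"].mean().sort_index()
    if len(means) < 3:
        raise ValueError(
            f"need >= 3 distinct concentrations, got {len(means)}"
        )
    if aggregate == "mean":
        c = means.index.to_numpy(dtype=float)
        y = means.to_numpy(dtype=float)
    else:
        c = df["concentration"].to_numpy(dtype=float)
        y = df["delta_ca"].to_numpy(dtype=float)

    max0 = float(means.max())
    if max0 <= 0:
        max0 = max(float(np.abs(y).max()), 1e-6)
    half = max0 / 2
    above = means[means >= half]
    ec50_0 = float(above.index[0]) if len(above) else float(means.index[-1])

    model = Model(_hill_model_logp, independent_vars=["concentration"])
    params = model.make_params(
        log_max=np.log(max0),
        log_ec50=np.log(ec50_0),
        log_hs=0.0,
    )
    params["log_hs"].set(min=np.log(HS_BOUNDS[0]), max=np.log(HS_BOUNDS[1]))
    result = model.fit(y, params, concentration=c)

    def _back(name):
        p = result.params[name]
        val = float(np.exp(p.value))
        err = float(val * p.stderr) if p.stderr is not None else None
        return val, err

    max_v, max_e = _back("log_max")
    ec50_v, ec50_e = _back("log_ec50")
    hs_v, hs_e = _back("log_hs")
    return DoseResponseFit(
        max_response=max_v,
        ec50=ec50_v,
        hill_coefficient=hs_v,
        max_stderr=max_e,
        ec50_stderr=ec50_e,
        hill_stderr=hs_e,
        residual_ss=float(np.sum(result.residual**2)),
        n_cells=len(df),
        converged=bool(result.success),
        message=str(result.message),
    )


@dataclass(frozen=True)
class ConditionComparison:
    ec50_fold_change: float
    max_ratio: float
    ec50_fold_interval: tuple[float, float] | None
    max_ratio_interval: tuple[float, float] | None
    n_bootstrap: int
    n_failed: int
    flagged: bool


def compare_conditions(
    control: list[CellResponse] | pd.DataFrame,
    treated: list[CellResponse] | pd.DataFrame,
    bootstrap_b: int = 200,
    seed: int | None = None,
    aggregate: str = "pooled",
) -> ConditionComparison:
    """EC50 fold change (treated/control) and Max ratio with bootstrap CIs.

    Cells are resampled with replacement within each condition; both fits are
    redone per resample and the 2.5/97.5 percentiles of the ratios form the
    interval.  Resamples where either fit fails are dropped; the comparison is
    flagged when more than 20% fail.  With ``bootstrap_b=0`` only the point
    estimates are computed.
    """
    ctrl = responses_to_frame(control)
    trt = responses_to_frame(treated)
    fit_c = fit_hill(ctrl, aggregate=aggregate)
    fit_t = fit_hill(trt, aggregate=aggregate)
    if not (fit_c.converged and fit_t.converged):
        raise ValueError("both condition fits must converge before comparison")
    fold = fit_t.ec50 / fit_c.ec50
    ratio = fit_t.max_response / fit_c.max_response
    if bootstrap_b <= 0:
        return ConditionComparison(fold, ratio, None, None, 0, 0, False)
    rng = np.random.default_rng(seed)
    folds, ratios = [], []
    n_failed = 0
    for _ in range(bootstrap_b):
        rc = ctrl.sample(n=len(ctrl), replace=True, random_state=rng)
        rt = trt.sample(n=len(trt), replace=True, random_state=rng)
        try:
            fc = fit_hill(rc, aggregate=aggregate)
            ft = fit_hill(rt, aggregate=aggregate)
            if not (fc.converged and ft.converged):
                raise RuntimeError("bootstrap fit did not converge")
            folds.append(ft.ec50 / fc.ec50)
            ratios.append(ft.max_response / fc.max_response)
        except (ValueError, RuntimeError):
            n_failed += 1
    flagged = n_failed > 0.2 * bootstrap_b
    if folds:
        fi = tuple(np.percentile(folds, [2.5, 97.5]))
        ri = tuple(np.percentile(ratios, [2.5, 97.5]))
    else:
        fi = ri = None
        flagged = True
    return ConditionComparison(fold, ratio, fi, ri, bootstrap_b, n_failed, flagged)


def classify_mcd_sensitivity(comparison: ConditionComparison) -> str:
    """Call a genotype cholesterol-depletion sensitive or not.

    ``"sensitive"`` when the bootstrap interval of the EC50 fold change
    excludes 1 (the treatment demonstrably moved the EC50);
    ``"insensitive"`` otherwise.
    """
    if comparison.ec50_fold_interval is None:
        raise ValueError("comparison carries no bootstrap interval")
    lo, hi = comparison.ec50_fold_interval
    return "sensitive" if (lo > 1.0 or hi < 1.0) else "insensitive"


def responses_to_frame(responses) -> pd.DataFrame:
    """Normalize list-of-CellResponse or DataFrame input to a tidy frame."""
    if isinstance(responses, pd.DataFrame):
        df = responses.copy()
        required = {"concentration", "delta_ca"}
        if not required <= set(df.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        return df
    return pd.DataFrame(
        [
            {
                "concentration": r.concentration,
                "delta_ca": r.delta_ca,
                "condition": r.condition,
                "genotype": r.genotype,
            }
            for r in responses
        ]
    )


def read_responses(path) -> pd.DataFrame:
    """Read a per-cell CSV (genotype, condition, concentration_uM, delta_ca_uM)."""
    df = pd.read_csv(path)
    rename = {"concentration_uM": "concentration", "delta_ca_uM": "delta_ca"}
    df = df.rename(columns=rename)
    if not {"concentration", "delta_ca"} <= set(df.columns):
        raise ValueError(
            "CSV needs concentration_uM and delta_ca_uM (or concentration/delta_ca)"
        )
    return df
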