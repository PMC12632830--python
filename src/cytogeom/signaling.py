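"""Dose-response analysis: 4PL fits, relative potency, phenotype calls.

Responses (e.g. median pSTAT fluorescence) are modeled with the
four-parameter logistic curve

    r(d) = bottom + (top − bottom) / (1 + (EC50 / d)^hill)

fitted by least squares on log-dose with multi-start initialisation.
Emax is the fitted span (top − bottom). Designs are normalised to a
wild-type reference measured in the same cells and readout: relative
Emax = Emax_design / Emax_reference, and Δlog10 EC50 = log10(EC50_ref /
EC50_design), positive when the design is more potent. The four-class
phenotype (full agonist-like, biased, partial, inactive) is called from
the relative Emax of two readouts (canonically pSTAT1 vs pSTAT5): a
biased agonist keeps pSTAT5 while attenuating pSTAT1; a partial agonist
attenuates both; below a floor on both it is inactive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("cytogeom")

__all__ = [
    "DoseResponseData",
    "FourPLParams",
    "PhenotypeCall",
    "BiasMetrics",
    "DoseResponseError",
    "fit_4pl",
    "relative_potency",
    "classify_phenotype",
    "bias_metrics",
]

DEFAULT_THRESHOLDS = {"high": 0.75, "floor": 0.10}


class DoseResponseError(ValueError):
    """Input data unsuitable for curve fitting."""


@dataclass
class DoseResponseData:
    """Tidy replicate measurements for one ligand × readout.

    ``doses`` and ``responses`` are parallel per-observation arrays
    (replicates appear as repeated dose values). Zero-dose baseline rows
    are allowed; they inform the bottom initialisation but are excluded
    from the log-dose regression.
    """

    ligand_id: str
    readout: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        if self.doses.shape != self.responses.shape:
            raise DoseResponseError("doses and responses must be parallel arrays")
        if not np.isfinite(self.responses).all() or not np.isfinite(self.doses).all():
            raise DoseResponseError("doses and responses must be finite")
        if (self.doses < 0).any():
            raise DoseResponseError("doses must be non-negative")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, ligand_id: str, readout: str) -> "DoseResponseData":
        sub = df[(df["ligand_id"] == ligand_id) & (df["readout"] == readout)]
        if len(sub) == 0:
            raise DoseResponseError(f"no rows for ({ligand_id}, {readout})")
        return cls(
            ligand_id=ligand_id,
            readout=readout,
            doses=sub["dose_molar"].to_numpy(float),
            responses=sub["response"].to_numpy(float),
        )


@dataclass(frozen=True)
class FourPLParams:
    """Canonicalised 4PL fit: ``top ≥ bottom``; for a decreasing curve the
    hill slope is negative (|hill| stays within the fit bounds [0.1, 10])."""

    bottom: float
    top: float
    ec50: float
    hill: float
    fit_rmse: float
    converged: bool
    no_response: bool = False

    @property
    def emax(self) -> float:
        return self.top - self.bottom

    def predict(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, float)
        return _model4pl(dose, self.bottom, self.top, math.log10(self.ec50), self.hill)


def _model4pl(dose, bottom, top, log_ec50, hill):
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + 10.0 ** (hill * (log_ec50 - np.log10(dose))))
    return bottom + (top - bottom) * frac


def fit_4pl(
    data: DoseResponseData,
    loss: str = "ols",
    max_iter: int = 2000,
    restarts: int = 4,
    seed: int = 0,
) -> FourPLParams:
    """Least-squares 4PL fit with heuristic multi-start initialisation.

    ``loss='ols'`` minimises squared residuals on raw responses;
    ``loss='log'`` on log responses (for multiplicative noise; requires
    positive responses). The hill magnitude is bounded to [0.1, 10] to
    prevent degenerate step fits on sparse dose grids. Deterministic
    given ``seed``.
    """
    nz = data.doses > 0
    doses = data.doses[nz]
    resp = data.responses[nz]
    zero_resp = data.responses[~nz]
    if len(np.unique(doses)) < 4:
        raise DoseResponseError(
            f"need >= 4 distinct nonzero doses, got {len(np.unique(doses))}"
        )

    scale = max(1.0, float(np.max(np.abs(resp))))
    if float(np.ptp(resp)) <= 1e-9 * scale:
        mean = float(np.mean(resp))
        return FourPLParams(
            bottom=mean, top=mean, ec50=float(np.exp(np.mean(np.log(doses)))),
            hill=1.0, fit_rmse=float(np.std(resp)), converged=True, no_response=True,
        )

    log_d = np.log10(doses)
    order = np.argsort(log_d)
    dose_means = pd.Series(resp).groupby(pd.Series(log_d)).mean()
    lo_mean = float(dose_means.iloc[0]) if len(zero_resp) == 0 else float(np.mean(zero_resp))
    hi_mean = float(dose_means.iloc[-1])

    # ec50 guess: dose whose mean response crosses the midpoint
    mid = 0.5 * (lo_mean + hi_mean)
    crossings = np.abs(dose_means.to_numpy() - mid)
    log_ec50_0 = float(dose_means.index[int(np.argmin(crossings))])

    if loss == "log":
        if (resp <= 0).any():
            raise DoseResponseError("log loss requires strictly positive responses")

        def residuals(theta):
            pred = _model4pl(doses, *theta)
            pred = np.clip(pred, 1e-12, None)
            return np.log(pred) - np.log(resp)
    elif loss == "ols":

        def residuals(theta):
            return _model4pl(doses, *theta) - resp
    else:
        raise ValueError(f"unknown loss {loss!r}")

    lb = [-np.inf, -np.inf, log_d.min() - 3.0, 0.1]
    ub = [np.inf, np.inf, log_d.max() + 3.0, 10.0]
    rng = np.random.default_rng(seed)
    inits = [(lo_mean, hi_mean, log_ec50_0, 1.0)]
    for _ in range(max(0, restarts - 1)):
        inits.append(
            (
                lo_mean + 0.1 * rng.normal() * abs(hi_mean - lo_mean),
                hi_mean + 0.1 * rng.normal() * abs(hi_mean - lo_mean),
                float(np.clip(log_ec50_0 + rng.normal(), lb[2], ub[2])),
                float(np.clip(10 ** rng.normal(0, 0.3), 0.1, 10.0)),
            )
        )

    best = None
    for x0 in inits:
        x0 = np.clip(np.asarray(x0, float), lb, ub)
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), max_nfev=max_iter, method="trf"
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise DoseResponseError("4PL optimisation failed from every start")

    bottom, top, log_ec50, hill = best.x
    converged = bool(best.success) and np.isfinite(best.cost)
    if top < bottom:
        # canonical form: increasing parameter order, signed hill
        bottom, top, hill = top, bottom, -hill
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2))) if loss == "ols" else float(
        np.sqrt(np.mean((_model4pl(doses, *best.x) - resp) ** 2))
    )
    no_resp = abs(top - bottom) <= 1e-6 * scale
    return FourPLParams(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0 ** log_ec50),
        hill=float(hill),
        fit_rmse=rmse,
        converged=converged,
        no_response=no_resp,
    )


def relative_potency(
    design: FourPLParams, reference: FourPLParams
) -> tuple[float, float]:
    """(relative Emax, Δlog10 EC50) of a design against the wild-type
    reference in the same readout; positive Δlog10 EC50 means more potent
    (a threefold potency gain is +log10 3 ≈ 0.477)."""
    if not (design.converged and reference.converged):
        raise DoseResponseError("both fits must be converged")
    if reference.no_response or reference.emax <= 0:
        raise DoseResponseError("reference has no measurable response")
    rel_emax = design.emax / reference.emax
    delta_log_ec50 = math.log10(reference.ec50 / design.ec50)
    return rel_emax, delta_log_ec50


@dataclass(frozen=True)
class PhenotypeCall:
    phenotype: str  # full_like | biased | partial | inactive
    rel_emax: dict[str, float]
    thresholds: dict[str, float]


def classify_phenotype(
    rel_emax_stat1: float,
    rel_emax_stat5: float,
    thresholds: dict[str, float] | None = None,
) -> PhenotypeCall:
    """Four-class signaling phenotype from relative Emax of two readouts.

    Rule order: both below the floor → inactive; pSTAT5 preserved
    (≥ high) with pSTAT1 attenuated (< high) → biased; both preserved →
    full agonist-like; anything else → partial. Thresholds are recorded
    in the call so every classification is re-derivable.
    """
    th = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if rel_emax_stat1 < 0 or rel_emax_stat5 < 0:
        raise ValueError("relative Emax must be non-negative")
    high, floor = th["high"], th["floor"]
    if rel_emax_stat1 < floor and rel_emax_stat5 < floor:
        cls = "inactive"
    elif rel_emax_stat5 >= high and rel_emax_stat1 < high:
        cls = "biased"
    elif rel_emax_stat5 >= high and rel_emax_stat1 >= high:
        cls = "full_like"
    else:
        cls = "partial"
    return PhenotypeCall(
        phenotype=cls,
        rel_emax={"pSTAT1": rel_emax_stat1, "pSTAT5": rel_emax_stat5},
        thresholds=th,
    )


@dataclass(frozen=True)
class BiasMetrics:
    """Signed signaling-bias summary; antisymmetric under readout swap."""

    delta_log_emax: float   # log2(relEmax_readout1 / relEmax_readout2)
    delta_log_ec50: float | None = None  # log10 potency shift vs wild type


def bias_metrics(
    rel_emax_readout1: float,
    rel_emax_readout2: float,
    delta_log_ec50: float | None = None,
) -> BiasMetrics:
    if rel_emax_readout1 <= 0 or rel_emax_readout2 <= 0:
        raise ValueError("bias metrics need strictly positive relative Emax values")
    return BiasMetrics(
        delta_log_emax=math.log2(rel_emax_readout1 / rel_emax_readout2),
        delta_log_ec50=delta_log_ec50,
    )
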