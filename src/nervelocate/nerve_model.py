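"""Probe-to-nerve distance prediction by nonlinear multiregression.

The distance model inverts two generative assumptions about stimulation
through an intervening medium of impedance magnitude ``Z``: the CMAP
amplitude at motor threshold scales as ``iMT / (d * Z)`` and the CMAP
latency grows with ``Z * d``.  Combining both gives the base model

    d = lambda1 * iMT / (CMAP * Z) + lambda2 * tL / Z + eta,

a three-parameter linear regression in the features
``x1 = iMT / (CMAP * Z)`` and ``x2 = tL / Z``.

The extended model replaces the constant offset ``eta`` with two structured
error functions built from the remaining trial features:

    eta1 = sum_j b1(j) * X1(j),   X1 = [1, theta1, theta2, R2_lin, iMT/Rp]
    eta2 = sum_j b2(j) * X2(j) + sum_k alpha(k) * exp(beta(k) * R~(k)),
           X2 = [Cp, R2_tau, Rs/Cp, tL],   R = [Rs, Rp]

for 15 free parameters in total (lambda1, lambda2, 5 x b1, 4 x b2, 2 x
alpha, 2 x beta).  All predictors are standardised internally (the
exponentials act on the *scaled* resistances; raw ohm-scale arguments would
overflow for any non-trivial beta) and the scaling is stored in the model,
so predictions are invariant to the raw feature units.  The base variant is
solved in closed form; the extended variant by bounded multi-start nonlinear
least squares seeded for bit-reproducibility.  One start is the base
solution embedded in the extended parameterisation, which guarantees the
extended training SSE never exceeds the base SSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitNotConverged,
    InvalidRecord,
    MissingFeature,
    RankDeficient,
    UnfittedModel,
)

__all__ = [
    "FeatureRecord",
    "FeatureReading",
    "FitConfig",
    "PredictionModel",
    "assemble_features",
    "build_design",
    "fit_model",
    "predict_distance",
]

Variant = Literal["base", "extended"]

N_PARAMS_EXTENDED = 15
_N_LINEAR = 11          # lambda1, lambda2, b1 (5), b2 (4)
_BASE_COLS = 3
_EXT_COLS = 13          # x1, x2, X1 (5), X2 (4), R (2)
_R_COLS = (11, 12)      # scaled Rs, Rp columns inside the extended design

BASE_FEATURE_NAMES = ("imt_over_cmap_z", "latency_term", "const")
EXTENDED_FEATURE_NAMES = BASE_FEATURE_NAMES[:2] + (
    "x1_const", "x1_theta1", "x1_theta2", "x1_lin_r2", "x1_imt_rp",
    "x2_cp", "x2_tau_r2", "x2_rs_cp", "x2_tl",
    "r_rs", "r_rp",
)


@dataclass
class FeatureRecord:
    """Assembled regression inputs for one stimulation trial.

    ``distance_mm`` is the training label (probe-to-nerve distance) and is
    ``None`` at prediction time.  ``subject``/``material`` are optional
    provenance tags used for grouped cross-validation.
    """

    i_mt: float                    # A, motor threshold
    cmap_amp: float                # V, CMAP amplitude entering the model
    z: float                       # ohm, impedance magnitude
    t_l: float                     # s, mean CMAP latency
    theta1: float                  # %/A, nerve-muscle slope
    theta2: float                  # %, nerve-muscle intercept
    lin_r_squared: float
    rs: float                      # ohm
    rp: float                      # ohm
    cp: float                      # F
    tau_r_squared: float
    distance_mm: float | None = None
    subject: int | None = None
    material: str | None = None


@dataclass(frozen=True)
class FeatureReading:
    """Resolution of ambiguous feature renderings.

    The source formulas render fractions by juxtaposition, so the latency
    term of the base model and two extended features admit a ratio or a
    product reading; the ratio reading is the dimensionally consistent
    default (see the methods note).
    """

    latency: Literal["ratio", "product"] = "ratio"   # tL/Z vs tL*Z
    x1_imt_rp: Literal["ratio", "product"] = "ratio"  # iMT/Rp vs iMT*Rp
    x2_rs_cp: Literal["ratio", "product"] = "ratio"   # Rs/Cp vs Rs*Cp


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for the extended-variant fit."""

    seed: int = 0
    n_starts: int = 8
    beta_bound: float = 10.0
    beta_init: float = 0.1
    max_nfev: int = 2000
    reading: FeatureReading = field(default_factory=FeatureReading)


def _require(value: float | None, name: str) -> float:
    if value is None or not np.isfinite(value):
        raise MissingFeature(f"record is missing required feature '{name}'")
    return float(value)


def assemble_features(
    record: FeatureRecord,
    variant: Variant = "base",
    reading: FeatureReading = FeatureReading(),
) -> np.ndarray:
    """Raw (unscaled) predictor vector for one record.

    Base: ``[iMT/(CMAP*Z), tL/Z, 1]``.  Extended appends X1, X2 and the raw
    resistances for the exponential terms (13 columns total).
    """
    i_mt = _require(record.i_mt, "i_mt")
    cmap = _require(record.cmap_amp, "cmap_amp")
    z = _require(record.z, "z")
    t_l = _require(record.t_l, "t_l")
    if z <= 0 or cmap <= 0 or i_mt <= 0:
        raise InvalidRecord(
            f"need i_mt, cmap_amp, z > 0 (got {i_mt:.3e}, {cmap:.3e}, {z:.3e})"
        )
    x1 = i_mt / (cmap * z)
    x2 = t_l / z if reading.latency == "ratio" else t_l * z
    base = [x1, x2, 1.0]
    if variant == "base":
        return np.array(base)

    theta1 = _require(record.theta1, "theta1")
    theta2 = _require(record.theta2, "theta2")
    lin_r2 = _require(record.lin_r_squared, "lin_r_squared")
    rs = _require(record.rs, "rs")
    rp = _require(record.rp, "rp")
    cp = _require(record.cp, "cp")
    tau_r2 = _require(record.tau_r_squared, "tau_r_squared")
    if rp <= 0 or cp <= 0:
        raise InvalidRecord(f"need rp, cp > 0 (got {rp:.3e}, {cp:.3e})")
    imt_rp = i_mt / rp if reading.x1_imt_rp == "ratio" else i_mt * rp
    rs_cp = rs / cp if reading.x2_rs_cp == "ratio" else rs * cp
    return np.array(
        base[:2]
        + [1.0, theta1, theta2, lin_r2, imt_rp]   # X1
        + [cp, tau_r2, rs_cp, t_l]                # X2
        + [rs, rp]                                # R (exponential terms)
    )


def build_design(
    records: Sequence[FeatureRecord],
    variant: Variant,
    reading: FeatureReading = FeatureReading(),
) -> np.ndarray:
    """Stack raw predictor vectors for a set of records."""
    return np.stack([assemble_features(r, variant, reading) for r in records])


def _fit_scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column center/scale; constant columns pass through untouched."""
    centers = X.mean(axis=0)
    scales = X.std(axis=0)
    const = scales <= 1e-12 * (np.abs(centers) + 1.0)
    centers[const] = 0.0
    scales[const] = 1.0
    return centers, scales


def _model_scaled(params: np.ndarray, Xs: np.ndarray, variant: Variant) -> np.ndarray:
    if variant == "base":
        return Xs @ params
    lin = Xs[:, :_N_LINEAR] @ params[:_N_LINEAR]
    alpha = params[_N_LINEAR : _N_LINEAR + 2]
    beta = params[_N_LINEAR + 2 : _N_LINEAR + 4]
    expo = alpha[0] * np.exp(beta[0] * Xs[:, _R_COLS[0]]) + alpha[1] * np.exp(
        beta[1] * Xs[:, _R_COLS[1]]
    )
    return lin + expo


@dataclass
class PredictionModel:
    """Fitted distance model: variant, coefficients, internal scaling."""

    variant: Variant
    params: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    reading: FeatureReading = field(default_factory=FeatureReading)
    diagnostics: dict = field(default_factory=dict)
    fitted: bool = False

    @property
    def feature_names(self) -> tuple[str, ...]:
        return BASE_FEATURE_NAMES if self.variant == "base" else EXTENDED_FEATURE_NAMES

    def predict(self, records: Sequence[FeatureRecord]) -> np.ndarray:
        """Predicted probe-to-nerve distance (mm) for each record."""
        if not self.fitted:
            raise UnfittedModel("model has not been fitted")
        X = build_design(records, self.variant, self.reading)
        Xs = (X - self.centers) / self.scales
        return _model_scaled(self.params, Xs, self.variant)

    def raw_base_coefficients(self) -> tuple[float, float, float]:
        """Base-variant coefficients (lambda1, lambda2, eta) in raw feature
        units, undoing the internal standardisation."""
        if self.variant != "base":
            raise ValueError("raw coefficients are only defined for the base variant")
        lam = self.params[:2] / self.scales[:2]
        eta = self.params[2] - float(np.sum(self.params[:2] * self.centers[:2] / self.scales[:2]))
        return float(lam[0]), float(lam[1]), eta

    # --- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.tolist(),
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "reading": asdict(self.reading),
            "diagnostics": self.diagnostics,
            "fitted": self.fitted,
            "feature_names": list(self.feature_names),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        return cls(
            variant=d["variant"],
            params=np.asarray(d["params"], dtype=float),
            centers=np.asarray(d["centers"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            reading=FeatureReading(**d.get("reading", {})),
            diagnostics=d.get("diagnostics", {}),
            fitted=d.get("fitted", True),
        )

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_base(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise RankDeficient(
            "base design matrix is rank-deficient; coefficients not identifiable"
        )
    coef, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
    sse = float(np.sum((Xs @ coef - y) ** 2))
    return coef, sse


def fit_model(
    records: Sequence[FeatureRecord],
    variant: Variant = "extended",
    config: FitConfig | None = None,
) -> PredictionModel:
    """Fit the distance model by (nonlinear) least squares on labelled records.

    Minimises the sum of squared distance residuals.  The base variant is the
    exact ordinary-least-squares solution on its three features.  The
    extended variant runs ``config.n_starts`` bounded trust-region starts:
    the embedded base solution, the 11-parameter linear subproblem solution
    with the documented beta initialisation, and seeded perturbations; the
    lowest-SSE solution wins.
    """
    config = config or FitConfig()
    y = np.array([r.distance_mm for r in records], dtype=float)
    if np.any(~np.isfinite(y)):
        raise MissingFeature("every training record needs a distance label")
    n_params = _BASE_COLS if variant == "base" else N_PARAMS_EXTENDED
    if len(records) < 2 * n_params:
        raise ValueError(
            f"need at least {2 * n_params} labelled records for the "
            f"{variant} variant, got {len(records)}"
        )

    X = build_design(records, variant, config.reading)
    centers, scales = _fit_scaling(X)
    Xs = (X - centers) / scales

    if variant == "base":
        coef, sse = _fit_base(Xs, y)
        return PredictionModel(
            variant="base", params=coef, centers=centers, scales=scales,
            reading=config.reading,
            diagnostics={"sse": sse, "n_records": len(records), "solver": "ols"},
            fitted=True,
        )

    # Linear subproblem (alpha = 0): OLS on the 11 linear columns.
    lin_cols = Xs[:, :_N_LINEAR]
    lin_coef, _, lin_rank, _ = np.linalg.lstsq(lin_cols, y, rcond=None)

    # Embedded base solution: lambda1, lambda2 and the intercept carried by
    # the constant X1(0) column; everything else zero.
    base_coef, base_sse = _fit_base(
        np.column_stack([Xs[:, 0], Xs[:, 1], np.ones(len(y))]), y
    )
    embed = np.zeros(_N_LINEAR)
    embed[[0, 1, 2]] = base_coef

    rng = np.random.default_rng(config.seed)
    b0 = config.beta_init
    starts: list[np.ndarray] = [
        np.concatenate([embed, [0.0, 0.0], [b0, -b0]]),
        np.concatenate([lin_coef, [0.0, 0.0], [b0, -b0]]),
    ]
    while len(starts) < config.n_starts:
        alpha0 = rng.normal(0.0, 0.3, size=2)
        beta0 = rng.uniform(-2.0, 2.0, size=2)
        starts.append(np.concatenate([lin_coef, alpha0, beta0]))

    lower = np.full(N_PARAMS_EXTENDED, -np.inf)
    upper = np.full(N_PARAMS_EXTENDED, np.inf)
    lower[-2:] = -config.beta_bound
    upper[-2:] = config.beta_bound

    def resid(p: np.ndarray) -> np.ndarray:
        return _model_scaled(p, Xs, "extended") - y

    best = None
    best_start = -1
    for k, x0 in enumerate(starts):
        sol = least_squares(
            resid, x0=np.clip(x0, lower, upper), bounds=(lower, upper),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=config.max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol
            best_start = k
    if best is None or best.status <= 0 and not np.isfinite(best.cost):
        raise FitNotConverged(
            "no extended-model start converged",
            diagnostics={"n_starts": len(starts)},
        )

    sse = float(np.sum(best.fun**2))
    return PredictionModel(
        variant="extended", params=best.x, centers=centers, scales=scales,
        reading=config.reading,
        diagnostics={
            "sse": sse,
            "base_sse": base_sse,
            "n_records": len(records),
            "n_starts": len(starts),
            "best_start": best_start,
            "status": int(best.status),
            "nfev": int(best.nfev),
            "linear_rank": int(lin_rank),
            "solver": "multistart-trf",
            "seed": config.seed,
        },
        fitted=True,
    )


def predict_distance(model: PredictionModel, record: FeatureRecord) -> float:
    """Predicted probe-to-nerve distance (mm) for a single record."""
    return float(model.predict([record])[0])
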