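"""Equilibrium-binding and kinetic regression models with CIs and R².

The seven model equations are the ones used throughout the eIF2B assays:

``one_phase_decay``        Y = (Y0 - Plateau)·exp(-K·X) + Plateau
``one_site_total``         Y = Bmax·X/(Kd + X) + NS·X + Background
``fourpl_inhibition``      Y = Bottom + (Top - Bottom)/(1 + 10^((LogIC50 - X)·HillSlope))
``two_phase_association``  Y = Y0 + SpanFast·(1 - e^(-KFast·X)) + SpanSlow·(1 - e^(-KSlow·X))
``two_phase_decay``        Y = Plateau + SpanFast·e^(-KFast·X) + SpanSlow·e^(-KSlow·X)
``one_site_specific``      Y = Bmax·X/(Kd + X)
``agonist_response``       Y = Bottom + X·(Top - Bottom)/(EC50 + X)

with SpanFast = |Plateau - Y0|-span · PercentFast·0.01 (and SpanSlow its
complement). X is time (min) for the kinetic models, concentration for the
binding models, and log10(concentration) for the four-parameter logistic
(whose midpoint parameter is LogIC50). Rate constants are in reciprocal X
units; the derived half-life is ln 2 / K.

Fitting is unweighted nonlinear least squares (Levenberg-Marquardt) with
data-driven initialisation and a few jittered restarts; 95% confidence
intervals use the t distribution on the asymptotic standard errors from the
covariance at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODELS",
    "ModelSpec",
    "KineticTrace",
    "FitResult",
    "FitError",
    "evaluate",
    "fit",
    "half_life",
    "half_life_from_rate",
    "percent_fast_dose_response",
]


class FitError(RuntimeError):
    """Non-convergence or an invalid fitting request."""


def _one_phase_decay(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    return (p["Y0"] - p["Plateau"]) * np.exp(-p["K"] * x) + p["Plateau"]


def _one_site_total(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    denom = p["Kd"] + x
    if np.any(denom == 0):
        raise ValueError("Kd + X = 0: model undefined")
    return p["Bmax"] * x / denom + p["NS"] * x + p["Background"]


def _fourpl_inhibition(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    return p["Bottom"] + (p["Top"] - p["Bottom"]) / (
        1.0 + 10.0 ** ((p["LogIC50"] - x) * p["HillSlope"])
    )


def _spans(total_span: float, percent_fast: float) -> tuple[float, float]:
    return total_span * percent_fast * 0.01, total_span * (100.0 - percent_fast) * 0.01


def _two_phase_association(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    span_fast, span_slow = _spans(p["Plateau"] - p["Y0"], p["PercentFast"])
    return (
        p["Y0"]
        + span_fast * (1.0 - np.exp(-p["KFast"] * x))
        + span_slow * (1.0 - np.exp(-p["KSlow"] * x))
    )


def _two_phase_decay(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    span_fast, span_slow = _spans(p["Y0"] - p["Plateau"], p["PercentFast"])
    return (
        p["Plateau"]
        + span_fast * np.exp(-p["KFast"] * x)
        + span_slow * np.exp(-p["KSlow"] * x)
    )


def _one_site_specific(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    denom = p["Kd"] + x
    if np.any(denom == 0):
        raise ValueError("Kd + X = 0: model undefined")
    return p["Bmax"] * x / denom


def _agonist_response(p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    return p["Bottom"] + x * (p["Top"] - p["Bottom"]) / (p["EC50"] + x)


@dataclass(frozen=True)
class ModelSpec:
    """One regression equation: parameter names, units, and the formula."""

    model_id: str
    params: tuple[str, ...]
    func: Callable[[Mapping[str, float], np.ndarray], np.ndarray]
    rate_param: str | None = None  # single rate constant → half-life defined
    positive: tuple[str, ...] = ()  # parameters bounded > 0
    x_kind: str = "time"  # "time" | "conc" | "log_conc"


MODELS: dict[str, ModelSpec] = {
    m.model_id: m
    for m in [
        ModelSpec("one_phase_decay", ("Y0", "Plateau", "K"), _one_phase_decay,
                  rate_param="K", positive=("K",)),
        ModelSpec("one_site_total", ("Bmax", "Kd", "NS", "Background"),
                  _one_site_total, positive=("Bmax", "Kd"), x_kind="conc"),
        ModelSpec("fourpl_inhibition", ("Bottom", "Top", "LogIC50", "HillSlope"),
                  _fourpl_inhibition, x_kind="log_conc"),
        ModelSpec("two_phase_association",
                  ("Y0", "Plateau", "PercentFast", "KFast", "KSlow"),
                  _two_phase_association, positive=("KFast", "KSlow")),
        ModelSpec("two_phase_decay",
                  ("Y0", "Plateau", "PercentFast", "KFast", "KSlow"),
                  _two_phase_decay, positive=("KFast", "KSlow")),
        ModelSpec("one_site_specific", ("Bmax", "Kd"), _one_site_specific,
                  positive=("Bmax", "Kd"), x_kind="conc"),
        ModelSpec("agonist_response", ("Bottom", "Top", "EC50"),
                  _agonist_response, positive=("EC50",), x_kind="conc"),
    ]
}


def _get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise FitError(f"unknown model {model!r}; known: {sorted(MODELS)}") from None


def evaluate(model: str | ModelSpec, params: Mapping[str, float], x) -> np.ndarray:
    """Pointwise evaluation of a model equation.

    Raises on missing parameters and on domain violations (negative
    concentrations for the binding models, Kd + X = 0).
    """
    spec = _get_model(model)
    missing = [p for p in spec.params if p not in params]
    if missing:
        raise FitError(f"{spec.model_id}: missing parameter(s) {missing}")
    x = np.asarray(x, dtype=float)
    if spec.x_kind == "conc" and np.any(x < 0):
        raise ValueError(f"{spec.model_id}: concentration X must be >= 0")
    return spec.func(params, x)


@dataclass
class KineticTrace:
    """A measured or simulated trace: X vs signal, optionally replicated."""

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None
    x_units: str = ""
    y_units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.x), dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)
        for rep in np.unique(self.replicate):
            xr = self.x[self.replicate == rep]
            if np.any(np.diff(xr) <= 0):
                raise ValueError(f"x must be strictly increasing within replicate {rep}")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KineticTrace":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "x" not in cols or "y" not in cols:
            raise ValueError(f"{path}: trace CSV needs 'x' and 'y' columns")
        rep = df[cols["replicate"]].to_numpy() if "replicate" in cols else None
        meta = {}
        for key in ("x_units", "y_units"):
            if key in cols:
                meta[key] = str(df[cols[key]].iloc[0])
        return cls(df[cols["x"]].to_numpy(), df[cols["y"]].to_numpy(), rep,
                   x_units=meta.get("x_units", ""), y_units=meta.get("y_units", ""))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y, "replicate": self.replicate})
        if self.x_units:
            df["x_units"] = self.x_units
        if self.y_units:
            df["y_units"] = self.y_units
        df.to_csv(path, index=False)


@dataclass
class FitResult:
    """Point estimates, 95% CIs, R² and diagnostics for one fitted trace."""

    model_id: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    ci95: dict[str, tuple[float, float]]
    r_squared: float
    residuals: np.ndarray
    n_points: int
    success: bool
    flags: list[str] = field(default_factory=list)
    derived: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model_id,
            "params": self.params,
            "stderr": self.stderr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "success": self.success,
            "flags": self.flags,
            "derived": self.derived,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _initial_guess(spec: ModelSpec, x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Data-driven starting values (documented heuristics, no magic fits)."""
    y0, y_end = float(y[0]), float(y[-1])
    span = max(float(y.max() - y.min()), 1e-12)
    x_span = max(float(x.max() - x.min()), 1e-12)
    k0 = 2.0 / x_span
    # refine the rate from the log-linearised first/last thirds when possible
    plateau = y_end
    ratio = (y0 - plateau), (float(y[len(y) // 2]) - plateau)
    if ratio[0] * ratio[1] > 0 and abs(ratio[1]) < abs(ratio[0]):
        x_mid = float(x[len(x) // 2]) - float(x[0])
        if x_mid > 0:
            k0 = math.log(abs(ratio[0] / ratio[1])) / x_mid or k0
    guesses = {
        "Y0": y0,
        "Plateau": y_end,
        "K": max(k0, 1e-6),
        "KFast": max(5 * k0, 1e-5),
        "KSlow": max(k0 / 5, 1e-7),
        "PercentFast": 50.0,
        "Bmax": span,
        "Kd": float(np.median(x[x > 0])) if np.any(x > 0) else 1.0,
        "NS": 0.0,
        "Background": float(y.min()),
        "Top": float(y.max()),
        "Bottom": float(y.min()),
        "HillSlope": 1.0 if y_end >= y0 else -1.0,
        "EC50": float(np.median(x[x > 0])) if np.any(x > 0) else 1.0,
    }
    # midpoint abscissa for the logistic / hyperbolic midpoint parameters
    half = 0.5 * (y.max() + y.min())
    idx = int(np.argmin(np.abs(y - half)))
    guesses["LogIC50"] = float(x[idx])
    if np.any(x > 0):
        x_half = float(x[idx])
        if x_half > 0:
            guesses["Kd"] = x_half
            guesses["EC50"] = x_half
    return {name: guesses[name] for name in spec.params}


def _make_lmfit_params(spec: ModelSpec, init: Mapping[str, float]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for name in spec.params:
        val = float(init[name])
        if name == "PercentFast":
            params.add(name, value=min(max(val, 1e-6), 100 - 1e-6), min=0.0, max=100.0)
        elif name in spec.positive:
            params.add(name, value=max(val, 1e-12), min=1e-12)
        else:
            params.add(name, value=val)
    return params


def _order_two_phase(values: dict[str, float], stderr: dict, ci: dict) -> None:
    """Canonicalise biphasic fits: KFast >= KSlow (swap relabels PercentFast)."""
    if values.get("KFast", 0.0) < values.get("KSlow", 0.0):
        for d in (values, stderr, ci):
            if "KFast" in d and "KSlow" in d:
                d["KFast"], d["KSlow"] = d["KSlow"], d["KFast"]
        values["PercentFast"] = 100.0 - values["PercentFast"]
        if "PercentFast" in ci and ci["PercentFast"] is not None:
            lo, hi = ci["PercentFast"]
            ci["PercentFast"] = (100.0 - hi, 100.0 - lo)


def fit(
    model: str | ModelSpec,
    trace: KineticTrace,
    x_window: tuple[float, float] | None = None,
    init: Mapping[str, float] | None = None,
    n_restarts: int = 5,
) -> FitResult:
    """Unweighted least-squares fit of a model to a trace.

    ``x_window`` restricts the fit to ``lo <= x <= hi`` (e.g. the first
    minutes of a dissociation). A handful of deterministically jittered
    restarts guards against poor starting values; the best solution by SSR is
    kept. Bad fits are not silently returned: non-convergence raises, and an
    R² < 0 is flagged.
    """
    spec = _get_model(model)
    x, y = trace.x, trace.y
    if x_window is not None:
        mask = (x >= x_window[0]) & (x <= x_window[1])
        x, y = x[mask], y[mask]
    order = np.lexsort((y, x))  # replicate-order independence
    x, y = x[order], y[order]
    if len(x) < len(spec.params) + 2:
        raise FitError(
            f"{spec.model_id}: need >= {len(spec.params) + 2} points, got {len(x)}"
        )

    base_init = dict(_initial_guess(spec, x, y))
    if init:
        base_init.update(init)

    def residual(lm_params: lmfit.Parameters) -> np.ndarray:
        values = {name: lm_params[name].value for name in spec.params}
        return spec.func(values, x) - y

    rng = np.random.default_rng(2021)
    best = None
    for attempt in range(n_restarts + 1):
        start = dict(base_init)
        if attempt > 0:
            for name in start:
                start[name] *= float(rng.uniform(0.5, 2.0))
                if name == "PercentFast":
                    start[name] = float(rng.uniform(10, 90))
        try:
            result = lmfit.minimize(residual, _make_lmfit_params(spec, start),
                                    method="leastsq")
        except Exception:
            continue
        ssr = float(np.sum(result.residual**2))
        if result.success and (best is None or ssr < best[0]):
            best = (ssr, result)
    if best is None:
        raise FitError(f"{spec.model_id}: no restart converged")
    ssr, result = best

    values = {name: float(result.params[name].value) for name in spec.params}
    stderr = {
        name: (float(result.params[name].stderr)
               if result.params[name].stderr is not None else None)
        for name in spec.params
    }
    dof = max(len(x) - result.nvarys, 1)
    tcrit = float(stats.t.ppf(0.975, dof))
    ci95 = {
        name: ((values[name] - tcrit * stderr[name], values[name] + tcrit * stderr[name])
               if stderr[name] is not None else None)
        for name in spec.params
    }
    if "KFast" in values:
        _order_two_phase(values, stderr, ci95)

    fitted = spec.func(values, x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ssr / sst if sst > 0 else float("nan")
    flags = []
    if not math.isnan(r_squared) and r_squared < 0:
        flags.append("r_squared_negative")
    if sst == 0:
        flags.append("degenerate_constant_y")
    if any(v is None for v in stderr.values()):
        flags.append("stderr_unavailable")

    derived = {}
    if spec.rate_param is not None and values[spec.rate_param] > 0:
        k = values[spec.rate_param]
        derived["half_life"] = math.log(2.0) / k
        if ci95[spec.rate_param] is not None:
            k_lo, k_hi = ci95[spec.rate_param]
            if k_lo > 0:
                derived["half_life_ci95"] = (math.log(2.0) / k_hi, math.log(2.0) / k_lo)

    return FitResult(spec.model_id, values, stderr, ci95, r_squared,
                     y - fitted, len(x), True, flags, derived)


def half_life_from_rate(k: float, ci95: tuple[float, float] | None = None) -> dict:
    """t_1/2 = ln 2 / K, with the CI propagated by monotonicity."""
    if k <= 0:
        raise ValueError(f"half-life undefined for rate constant K = {k}")
    out = {"half_life": math.log(2.0) / k}
    if ci95 is not None:
        k_lo, k_hi = ci95
        if k_lo <= 0:
            raise ValueError("half-life CI undefined: lower rate bound <= 0")
        out["half_life_ci95"] = (math.log(2.0) / k_hi, math.log(2.0) / k_lo)
    return out


def half_life(fit_result: FitResult) -> dict:
    """Half-life from a fitted single-rate model (ln 2 / K)."""
    spec = _get_model(fit_result.model_id)
    if spec.rate_param is None:
        raise ValueError(f"{spec.model_id} has no single rate constant")
    return half_life_from_rate(
        fit_result.params[spec.rate_param], fit_result.ci95.get(spec.rate_param)
    )


def percent_fast_dose_response(
    concentrations: Sequence[float],
    fits: Sequence[FitResult | float],
) -> FitResult:
    """EC50 of the %Fast of biphasic dissociations vs ligand concentration.

    Accepts two-phase-decay FitResults (their PercentFast is extracted) or raw
    %Fast values, and fits them to the hyperbolic agonist-response model.
    """
    if len(concentrations) < 4:
        raise FitError("dose-response needs >= 4 concentrations")
    pf = []
    for f in fits:
        val = f.params["PercentFast"] if isinstance(f, FitResult) else float(f)
        if not 0.0 <= val <= 100.0:
            raise ValueError(f"PercentFast {val} outside [0, 100]")
        pf.append(val)
    pf = np.asarray(pf, float)
    conc = np.asarray(concentrations, float)
    order = np.argsort(conc)
    trace = KineticTrace(conc[order], pf[order], x_units="conc", y_units="%")
    if np.allclose(pf, pf[0]):
        res = FitResult("agonist_response",
                        {"Bottom": float(pf[0]), "Top": float(pf[0]), "EC50": float("nan")},
                        {}, {}, float("nan"), pf - pf.mean(), len(pf), False,
                        ["degenerate_constant_y"])
        return res
    return fit("agonist_response", trace)
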