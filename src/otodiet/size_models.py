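"""Predictor-to-fish-size regression models and AIC-based selection.

Three mean functions relate an otolith feature length x (OL, SL or CL, mm)
to fish size y (total length FTL in mm, or weight FW in g):

    linear    y = b0 + b1 * x
    logistic  y = A / (1 + exp(-k (x - x0)))
    gompertz  y = A * exp(-exp(-k (x - x0)))

Fits are ordinary least squares on the raw response scale. Candidate forms
are compared by least-squares AIC = n ln(RSS/n) + 2 (p + 1) with two
caveats: the simpler linear model is preferred when its dAIC <= 2, and if
one form wins for two of the three predictors of a species it is imposed on
all three for consistency. A packaged set of 24 published models (4 species
x 3 predictors x {FTL, FW}) ships with the package.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._stats import WithinUnitTest, within_unit_permutation
from .types import ReferenceOtolith, Species

__all__ = [
    "Form",
    "Predictor",
    "Response",
    "SizeModel",
    "ModelSelection",
    "fit_curve",
    "fit_model",
    "select_model",
    "predict_size",
    "invert_size_model",
    "measured_minus_predicted",
    "load_packaged_models",
    "packaged_model",
]


class Form(str, enum.Enum):
    LINEAR = "linear"
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"


class Predictor(str, enum.Enum):
    OL = "OL"
    SL = "SL"
    CL = "CL"


class Response(str, enum.Enum):
    FTL = "FTL"
    FW = "FW"


class SelectionRationale(str, enum.Enum):
    LOWEST_AIC = "lowest_aic"
    LINEAR_WITHIN_2 = "linear_within_2"
    MAJORITY_FORM = "majority_form"


def _linear(x, b0, b1):
    return b0 + b1 * x


def _logistic(x, a, k, x0):
    return a / (1.0 + np.exp(-k * (x - x0)))


def _gompertz(x, a, k, x0):
    return a * np.exp(-np.exp(-k * (x - x0)))


_FUNCS = {Form.LINEAR: _linear, Form.LOGISTIC: _logistic, Form.GOMPERTZ: _gompertz}
_NPARAMS = {Form.LINEAR: 2, Form.LOGISTIC: 3, Form.GOMPERTZ: 3}


@dataclass
class SizeModel:
    """One fitted or packaged predictor -> fish-size equation."""

    species: Species
    predictor: Predictor
    response: Response
    form: Form
    params: dict[str, float]
    r2: float | None = None
    aic: float | None = None
    n: int | None = None
    x_range: tuple[float, float] | None = None  # fitted predictor range, mm

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        self.predictor = Predictor(self.predictor)
        self.response = Response(self.response)
        self.form = Form(self.form)
        expected = {Form.LINEAR: ("b0", "b1")}.get(self.form, ("A", "k", "x0"))
        if set(self.params) != set(expected):
            raise ValueError(f"{self.form.value} model needs params {expected}")

    def __call__(self, x):
        return predict_size(self, x)

    def param_vector(self) -> np.ndarray:
        order = ("b0", "b1") if self.form is Form.LINEAR else ("A", "k", "x0")
        return np.array([self.params[p] for p in order], dtype=float)

    def to_dict(self) -> dict:
        return {
            "species": self.species.value,
            "predictor": self.predictor.value,
            "response": self.response.value,
            "form": self.form.value,
            "params": dict(self.params),
            "r2": self.r2,
            "aic": self.aic,
            "n": self.n,
            "x_range": list(self.x_range) if self.x_range else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SizeModel":
        d = dict(d)
        xr = d.get("x_range")
        d["x_range"] = tuple(xr) if xr else None
        return cls(**d)


def save_models(models: Iterable[SizeModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2))


def load_models(path: str | Path) -> list[SizeModel]:
    return [SizeModel.from_dict(d) for d in json.loads(Path(path).read_text())]


def predict_size(model: SizeModel, x, *, strict: bool = True) -> np.ndarray | float:
    """Evaluate the stored mean function; vectorized over ``x``.

    ``strict=False`` permits non-positive x for analytic boundary checks
    (e.g. the linear intercept at x = 0).
    """
    arr = np.asarray(x, dtype=float)
    if strict and np.any(arr <= 0):
        raise ValueError("predictor lengths must be positive")
    out = _FUNCS[model.form](arr, *model.param_vector())
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def extrapolates(model: SizeModel, x) -> np.ndarray:
    """Boolean mask of predictions outside the fitted predictor range.

    Eroded prey otoliths are, by construction, below-range in OL; such
    predictions are permitted but flaggable. Packaged models carry no range
    and never flag.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if model.x_range is None:
        return np.zeros(arr.shape, dtype=bool)
    lo, hi = model.x_range
    return (arr < lo) | (arr > hi)


def invert_size_model(model: SizeModel, y) -> np.ndarray | float:
    """Predictor length at which the model attains size ``y`` (exact inverse)."""
    arr = np.asarray(y, dtype=float)
    p = model.params
    if model.form is Form.LINEAR:
        out = (arr - p["b0"]) / p["b1"]
    elif model.form is Form.LOGISTIC:
        if np.any(arr >= p["A"]) or np.any(arr <= 0):
            raise ValueError("logistic inverse needs 0 < y < A")
        out = p["x0"] - np.log(p["A"] / arr - 1.0) / p["k"]
    else:
        if np.any(arr >= p["A"]) or np.any(arr <= 0):
            raise ValueError("gompertz inverse needs 0 < y < A")
        out = p["x0"] - np.log(-np.log(arr / p["A"])) / p["k"]
    return float(out) if np.isscalar(y) else out


def aic_least_squares(rss: float, n: int, n_params: int, *, corrected: bool = False) -> float:
    """AIC for a least-squares fit: n ln(RSS/n) + 2 (p + 1), where the +1
    counts the error variance. ``corrected=True`` adds the small-sample AICc
    term."""
    if n <= 0:
        raise ValueError("n must be positive")
    k = n_params + 1
    rss = max(rss, 1e-300)  # guard log on perfect fits
    aic = n * math.log(rss / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            return float("inf")
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _self_start(x: np.ndarray, y: np.ndarray, form: Form) -> np.ndarray:
    """Deterministic self-starting values for the sigmoid fits.

    A0 = 1.05 max(y); x0 from the observation nearest the curve midpoint
    (A0/2 logistic, A0/e gompertz); k0 from an OLS fit of the linearizing
    transform against x.
    """
    a0 = 1.05 * float(np.max(y))
    target = a0 / 2 if form is Form.LOGISTIC else a0 / math.e
    x00 = float(x[np.argmin(np.abs(y - target))])
    frac = np.clip(y / a0, 1e-6, 1 - 1e-6)
    if form is Form.LOGISTIC:
        z = np.log(frac / (1 - frac))
    else:
        z = -np.log(-np.log(frac))
    denom = float(np.sum((x - x.mean()) ** 2))
    k0 = float(np.sum((x - x.mean()) * (z - z.mean())) / denom) if denom > 0 else 0.1
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 0.1
    return np.array([a0, k0, x00])


def fit_curve(x, y, form: Form, *, seed: int = 0,
              aicc: bool = False) -> tuple[np.ndarray, float, float]:
    """Least-squares fit of one mean function; returns (params, r2, aic).

    Nonlinear fits use deterministic self-starting values with up to three
    seeded jittered restarts before declaring non-convergence. A constant
    response yields the degenerate linear fit (slope 0, r2 = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    n = x.size
    form = Form(form)

    if form is Form.LINEAR:
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            params = np.array([float(y[0]) if n else 0.0, 0.0])
            return params, 0.0, aic_least_squares(0.0, n, 2, corrected=aicc)
        b1, b0 = np.polyfit(x, y, 1)
        params = np.array([b0, b1])
        rss = float(np.sum((y - _linear(x, *params)) ** 2))
        return params, _r2(rss, tss), aic_least_squares(rss, n, 2, corrected=aicc)

    func = _FUNCS[form]
    p0 = _self_start(x, y, form)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    best: tuple[float, np.ndarray] | None = None
    for attempt in range(4):
        # the asymptote can sit far above the data (the fitted range may
        # cover only the rising limb), so retries inflate A progressively
        start = p0.copy()
        if attempt:
            start = p0 * rng.uniform(0.85, 1.15, size=3)
            start[0] = p0[0] * 5.0 ** attempt
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, _ = curve_fit(func, x, y, p0=start, maxfev=20000)
            resid = y - func(x, *params)
            if not np.all(np.isfinite(resid)):
                raise RuntimeError("non-finite fit")
            rss = float(np.sum(resid ** 2))
            if best is None or rss < best[0]:
                best = (rss, np.asarray(params, dtype=float))
        except Exception as exc:  # retry from a jittered start
            last_err = exc
    if best is None:
        # fall back to profiling the asymptote out: for fixed (k, x0) the
        # shape g(x) is known and A solves by linear least squares
        best = _fit_profiled(x, y, form, p0)
        if best is None:
            raise RuntimeError(f"{form.value} fit failed to converge: {last_err}")
    rss, params = best
    tss = float(np.sum((y - y.mean()) ** 2))
    return params, _r2(rss, tss), aic_least_squares(rss, n, 3, corrected=aicc)


def _fit_profiled(x, y, form: Form, p0) -> tuple[float, np.ndarray] | None:
    from scipy.optimize import minimize

    def shape(k, x0):
        z = -k * (x - x0)
        if form is Form.LOGISTIC:
            return 1.0 / (1.0 + np.exp(z))
        return np.exp(-np.exp(z))

    def rss_of(theta):
        k, x0 = math.exp(theta[0]), theta[1]
        g = shape(k, x0)
        denom = float(np.sum(g * g))
        if denom <= 0 or not np.isfinite(denom):
            return 1e30
        a = float(np.sum(y * g) / denom)
        r = float(np.sum((y - a * g) ** 2))
        return r if np.isfinite(r) else 1e30

    best = None
    for k_scale in (1.0, 0.3, 3.0):
        res = minimize(rss_of, x0=[math.log(max(p0[1], 1e-6) * k_scale), p0[2]],
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 8000})
        r = rss_of(res.x)
        if np.isfinite(r) and r < 1e30 and (best is None or r < best[0]):
            best = (r, res.x)
    if best is None:
        return None
    k, x0 = math.exp(best[1][0]), best[1][1]
    g = shape(k, x0)
    a = float(np.sum(y * g) / np.sum(g * g))
    rss = float(np.sum((y - a * g) ** 2))
    return rss, np.array([a, k, x0])


def _r2(rss: float, tss: float) -> float:
    if tss == 0:
        return 0.0
    return float(np.clip(1.0 - rss / tss, 0.0, 1.0))


_RESP_FIELD = {Response.FTL: "ftl_mm", Response.FW: "fw_g"}
_PRED_FIELD = {Predictor.OL: "ol_mm", Predictor.SL: "sl_mm", Predictor.CL: "cl_mm"}


def _xy(reference: Sequence[ReferenceOtolith], species: Species,
        predictor: Predictor, response: Response) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for o in reference:
        if o.species is not Species(species):
            continue
        xv = getattr(o, _PRED_FIELD[Predictor(predictor)])
        yv = getattr(o, _RESP_FIELD[Response(response)])
        if xv is not None and yv is not None:
            xs.append(xv)
            ys.append(yv)
    return np.asarray(xs), np.asarray(ys)


def fit_model(reference: Sequence[ReferenceOtolith], species: Species,
              predictor: Predictor, response: Response, form: Form, *,
              seed: int = 0, aicc: bool = False) -> SizeModel:
    """Fit one species/predictor/response/form combination on reference rows."""
    x, y = _xy(reference, species, predictor, response)
    if x.size < 10:
        raise ValueError(
            f"{Species(species).value} {Predictor(predictor).value}->"
            f"{Response(response).value}: need >= 10 complete rows, have {x.size}")
    try:
        params, r2, aic = fit_curve(x, y, Form(form), seed=seed, aicc=aicc)
    except RuntimeError as exc:
        raise RuntimeError(
            f"{Species(species).value} {Predictor(predictor).value}->"
            f"{Response(response).value} {Form(form).value}: {exc}") from exc
    names = ("b0", "b1") if Form(form) is Form.LINEAR else ("A", "k", "x0")
    return SizeModel(species=Species(species), predictor=Predictor(predictor),
                     response=Response(response), form=Form(form),
                     params=dict(zip(names, map(float, params))),
                     r2=r2, aic=aic, n=int(x.size),
                     x_range=(float(x.min()), float(x.max())))


@dataclass
class ModelSelection:
    """Outcome of the dAIC selection protocol for one species/response."""

    species: Species
    response: Response
    aic_table: dict[Predictor, dict[Form, float]]
    chosen: dict[Predictor, Form]
    rationale: dict[Predictor, SelectionRationale]
    majority_applied: bool = False


def select_model(species: Species, response: Response,
                 aic_table: dict) -> ModelSelection:
    """Apply the two-caveat AIC protocol to a 3 predictor x 3 form table.

    Per predictor the lowest-AIC form wins unless the linear model is within
    dAIC <= 2 of it; then, if a single form won for at least two predictors,
    that form is imposed on all three (majority consistency pass).
    """
    table: dict[Predictor, dict[Form, float]] = {}
    for pred in Predictor:
        if pred not in aic_table and pred.value not in aic_table:
            raise ValueError(f"AIC table missing predictor {pred.value}")
        row = aic_table.get(pred, aic_table.get(pred.value))
        table[pred] = {}
        for form in Form:
            if form not in row and form.value not in row:
                raise ValueError(f"AIC table missing {pred.value}/{form.value}")
            table[pred][form] = float(row.get(form, row.get(form.value)))

    chosen: dict[Predictor, Form] = {}
    rationale: dict[Predictor, SelectionRationale] = {}
    for pred, row in table.items():
        best = min(row, key=row.get)
        if best is not Form.LINEAR and row[Form.LINEAR] - row[best] <= 2.0:
            chosen[pred] = Form.LINEAR
            rationale[pred] = SelectionRationale.LINEAR_WITHIN_2
        else:
            chosen[pred] = best
            rationale[pred] = SelectionRationale.LOWEST_AIC

    counts: dict[Form, int] = {}
    for f in chosen.values():
        counts[f] = counts.get(f, 0) + 1
    majority = max(counts, key=counts.get)
    applied = False
    if counts[majority] >= 2 and counts[majority] < 3:
        for pred in table:
            if chosen[pred] is not majority:
                chosen[pred] = majority
                rationale[pred] = SelectionRationale.MAJORITY_FORM
        applied = True
    return ModelSelection(species=Species(species), response=Response(response),
                          aic_table=table, chosen=chosen, rationale=rationale,
                          majority_applied=applied)


def measured_minus_predicted(models: dict, reference: Sequence[ReferenceOtolith],
                             *, b: int = 2000, seed: int = 0,
                             ) -> tuple[list[dict], WithinUnitTest]:
    """Per-fish residuals (measured - predicted size) for each predictor,
    plus a within-fish label-permutation test of predictor differences.

    ``models`` maps each predictor (OL, SL, CL) to a SizeModel with a common
    response. Fish missing any predictor are dropped. The test statistic is
    the maximum absolute pairwise difference of mean residuals; the null is
    built by permuting predictor labels within fish.
    """
    models = {Predictor(k): v for k, v in models.items()}
    if set(models) != set(Predictor):
        raise ValueError("need one model per predictor OL, SL, CL")
    responses = {m.response for m in models.values()}
    if len(responses) != 1:
        raise ValueError("all models must share the same response")
    response = responses.pop()
    if b < 100:
        warnings.warn(f"B={b} permutations is very small; p-values will be coarse")

    rows = []
    dropped = 0
    for o in reference:
        yv = getattr(o, _RESP_FIELD[response])
        xs = {p: getattr(o, _PRED_FIELD[p]) for p in Predictor}
        if yv is None or any(v is None for v in xs.values()):
            dropped += 1
            continue
        resid = {p: yv - predict_size(models[p], xs[p]) for p in Predictor}
        rows.append({"fish_id": o.fish_id, "measured": yv,
                     **{p.value: resid[p] for p in Predictor}})
    if not rows:
        raise ValueError("no fish with all three predictors measured")

    mat = np.array([[r["OL"], r["SL"], r["CL"]] for r in rows])
    test = within_unit_permutation(mat, [p.value for p in Predictor], b=b, seed=seed)
    return rows, test


# --- packaged published models -------------------------------------------

_FIXTURE = "table3_models.json"


def load_packaged_models() -> list[SizeModel]:
    """The 24 published best-fit models (4 species x OL/SL/CL x FTL/FW).

    Verified against a stored checksum; a corrupted fixture raises.
    """
    text = resources.files("otodiet.data").joinpath(_FIXTURE).read_text()
    obj = json.loads(text)
    payload = json.dumps(obj["models"], sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(payload.encode()).hexdigest()
    if digest != obj["sha256"]:
        raise ValueError("packaged model fixture is corrupted (checksum mismatch)")
    models = [SizeModel.from_dict(d) for d in obj["models"]]
    if len(models) != 24:
        raise ValueError(f"expected 24 packaged models, found {len(models)}")
    return models


def packaged_model(species: Species, predictor: Predictor,
                   response: Response) -> SizeModel:
    species, predictor, response = Species(species), Predictor(predictor), Response(response)
    for m in load_packaged_models():
        if (m.species, m.predictor, m.response) == (species, predictor, response):
            return m
    raise KeyError(f"no packaged model for {species.value}/{predictor.value}/{response.value}")
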