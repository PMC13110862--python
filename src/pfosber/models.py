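"""Continuous dose-response model suite (EPA BMDS forms).

Mean functions, in the parameterization used throughout:

* ``Linear``  f(d) = β0 + β1·d
* ``Poly2``   f(d) = β0 + β1·d + β2·d²
* ``Poly3``   f(d) = β0 + β1·d + β2·d² + β3·d³
* ``Exp3``    f(d) = a·exp(s·(b·d)^g), sign s ∈ {−1, +1}
* ``Exp5``    f(d) = a·(c − (c − 1)·exp(−(b·d)^g))
* ``Hill``    f(d) = γ + v·dⁿ / (kⁿ + dⁿ)

Responses are modelled as i.i.d. normal with constant variance σ² around the
mean function; maximizing that likelihood is ordinary least squares on the
mean parameters with σ̂² = RSS/n.  The "restricted" convention bounds the
exponential/Hill power parameters at 1 (no supralinear curvature at zero)
and constrains polynomial dose coefficients to a common sign (monotone
curves); set ``restricted=False`` to lift both.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import least_squares, lsq_linear

MODEL_IDS = ("Linear", "Poly2", "Poly3", "Exp3", "Exp5", "Hill")

#: number of mean-model parameters (σ adds one more in AIC accounting)
N_PARAMS = {"Linear": 2, "Poly2": 3, "Poly3": 4, "Exp3": 3, "Exp5": 4, "Hill": 4}

#: nesting used by the likelihood-ratio model-selection step
POLY_FAMILY = ("Linear", "Poly2", "Poly3")
EXP_FAMILY = ("Exp3", "Exp5")

_POWER_MAX = 18.0  # BMDS convention for Hill n and Exp g


def evaluate_model(model_id: str, params: dict, dose) -> np.ndarray | float:
    """Mean response of ``model_id`` with ``params`` at ``dose`` (nM)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    p = params
    if model_id == "Linear":
        out = p["beta0"] + p["beta1"] * d
    elif model_id == "Poly2":
        out = p["beta0"] + p["beta1"] * d + p["beta2"] * d**2
    elif model_id == "Poly3":
        out = p["beta0"] + p["beta1"] * d + p["beta2"] * d**2 + p["beta3"] * d**3
    elif model_id == "Exp3":
        _check(p["a"] > 0 and p["b"] > 0 and p["g"] >= 1, "Exp3 requires a>0, b>0, g>=1")
        _check(p["s"] in (-1, 1, -1.0, 1.0), "Exp3 sign s must be ±1")
        # exponent clipped far above any physically meaningful value to keep
        # the optimizer's objective finite when a start overshoots
        out = p["a"] * np.exp(np.clip(p["s"] * (p["b"] * d) ** p["g"], -700.0, 700.0))
    elif model_id == "Exp5":
        _check(p["a"] > 0 and p["b"] > 0 and p["g"] >= 1 and p["c"] > 0, "Exp5 requires a,b,c>0, g>=1")
        out = p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-np.clip((p["b"] * d) ** p["g"], 0.0, 700.0)))
    elif model_id == "Hill":
        _check(p["k"] > 0 and p["n"] >= 1, "Hill requires k>0, n>=1")
        dn = d ** p["n"]
        out = p["gamma"] + p["v"] * dn / (p["k"] ** p["n"] + dn)
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return float(out) if np.ndim(out) == 0 else out


def _check(ok: bool, msg: str) -> None:
    if not ok:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# fitting machinery: parameter vector <-> dict, bounds, starting points
# ---------------------------------------------------------------------------

_PARAM_NAMES = {
    "Linear": ("beta0", "beta1"),
    "Poly2": ("beta0", "beta1", "beta2"),
    "Poly3": ("beta0", "beta1", "beta2", "beta3"),
    "Exp3": ("a", "b", "g"),
    "Exp5": ("a", "b", "c", "g"),
    "Hill": ("gamma", "v", "k", "n"),
}


def param_names(model_id: str) -> tuple[str, ...]:
    return _PARAM_NAMES[model_id]


def pack(model_id: str, params: dict) -> np.ndarray:
    return np.array([params[k] for k in _PARAM_NAMES[model_id]], dtype=float)


def unpack(model_id: str, x: np.ndarray, sign: float | None = None) -> dict:
    d = dict(zip(_PARAM_NAMES[model_id], (float(v) for v in x)))
    if model_id == "Exp3":
        d["s"] = float(sign if sign is not None else 1.0)
    return d


def bounds(model_id: str, doses: np.ndarray, restricted: bool = True):
    """(lower, upper) bounds on the packed mean-parameter vector."""
    dmax = float(np.max(doses))
    dmin_pos = float(np.min(doses[doses > 0]))
    g_lo = 1.0 if restricted else 1e-2
    if model_id in ("Linear", "Poly2", "Poly3"):
        k = N_PARAMS[model_id]
        return np.full(k, -np.inf), np.full(k, np.inf)
    if model_id == "Exp3":
        return (
            np.array([1e-8, 1e-6 / dmax, g_lo]),
            np.array([np.inf, 10.0 / dmin_pos, _POWER_MAX]),
        )
    if model_id == "Exp5":
        return (
            np.array([1e-8, 1e-6 / dmax, 1e-6, g_lo]),
            np.array([np.inf, 10.0 / dmin_pos, 1e6, _POWER_MAX]),
        )
    if model_id == "Hill":
        n_lo = 1.0 if restricted else 1e-2
        return (
            np.array([-np.inf, -np.inf, dmin_pos / 100.0, n_lo]),
            np.array([np.inf, np.inf, dmax * 100.0, _POWER_MAX]),
        )
    raise ValueError(model_id)


def starting_points(model_id: str, doses: np.ndarray, responses: np.ndarray):
    """Deterministic multi-start grid for the nonlinear models.

    Anchored on simple data summaries (control mean, top-dose shift) crossed
    with a log-spaced grid of potency parameters and a couple of powers.
    """
    dmax = float(np.max(doses))
    dmin_pos = float(np.min(doses[doses > 0]))
    y0 = float(np.mean(responses[doses == np.min(doses)]))
    ytop = float(np.mean(responses[doses == dmax]))
    shift = ytop - y0
    if shift == 0.0:
        shift = 1e-3
    mids = np.geomspace(dmin_pos, dmax, 3)  # candidate EC50-scale values
    starts = []
    if model_id == "Exp3":
        a0 = max(abs(y0), 1e-6)
        for m, g in itertools.product(mids, (1.0, 2.0)):
            starts.append(np.array([a0, 1.0 / m, g]))
    elif model_id == "Exp5":
        a0 = max(abs(y0), 1e-6)
        c0 = max((y0 + shift) / a0, 1e-3)
        for m, g in itertools.product(mids, (1.0, 2.0)):
            starts.append(np.array([a0, 1.0 / m, c0, g]))
    elif model_id == "Hill":
        for m, n in itertools.product(mids, (1.0, 2.0)):
            starts.append(np.array([y0, shift, m, n]))
    else:
        raise ValueError(f"{model_id} is fit in closed form; no starts needed")
    return starts


def fit_mean_params(model_id: str, doses: np.ndarray, responses: np.ndarray, restricted: bool = True):
    """Least-squares estimate of the mean parameters.

    Returns ``(params_dict, rss, converged)``.  Polynomial members are solved
    exactly by linear least squares; the nonlinear members use bounded
    Levenberg/TRF with a deterministic multi-start.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if model_id in ("Linear", "Poly2", "Poly3"):
        deg = {"Linear": 1, "Poly2": 2, "Poly3": 3}[model_id]
        X = np.vander(doses, deg + 1, increasing=True)
        if restricted and deg > 1:
            # BMDS restricted polynomials: dose coefficients share one sign,
            # so the curve is monotone; fit both signs, keep the better RSS
            best_c, best_rss = None, np.inf
            for sgn in (1.0, -1.0):
                lb = np.r_[-np.inf, np.zeros(deg)] if sgn > 0 else np.r_[-np.inf, np.full(deg, -np.inf)]
                ub = np.r_[np.inf, np.full(deg, np.inf)] if sgn > 0 else np.r_[np.inf, np.zeros(deg)]
                sol = lsq_linear(X, responses, bounds=(lb, ub))
                rss_s = float(np.sum((responses - X @ sol.x) ** 2))
                if rss_s < best_rss:
                    best_c, best_rss = sol.x, rss_s
            coef, rss = best_c, best_rss
        else:
            coef, *_ = np.linalg.lstsq(X, responses, rcond=None)
            rss = float(np.sum((responses - X @ coef) ** 2))
        params = {f"beta{i}": float(c) for i, c in enumerate(coef)}
        return params, rss, True

    sign = None
    if model_id == "Exp3":
        y0 = float(np.mean(responses[doses == np.min(doses)]))
        ytop = float(np.mean(responses[doses == np.max(doses)]))
        sign = 1.0 if ytop >= y0 else -1.0

    lo, hi = bounds(model_id, doses, restricted)
    best = None
    for x0 in starting_points(model_id, doses, responses):
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi - 1e-12))

        def resid(x):
            with np.errstate(over="ignore", invalid="ignore"):
                mu = evaluate_model(model_id, unpack(model_id, x, sign), doses)
            r = responses - mu
            return np.where(np.isfinite(r), r, 1e6)

        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                x_scale=np.maximum(np.abs(x0), 1e-4),
                                xtol=1e-10, ftol=1e-10, max_nfev=300)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if np.isfinite(rss) and (best is None or rss < best[1]):
            best = (sol.x, rss, bool(sol.success))
    if best is None:
        return {}, np.inf, False
    x, rss, ok = best
    return unpack(model_id, x, sign), rss, ok
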