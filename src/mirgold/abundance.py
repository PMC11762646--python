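"""Maximum-likelihood fitting of discrete abundance models to degree data.

Each node's degree (support x = 1, 2, 3, ...) is one observation.  Three
candidate models are fitted and compared by AIC (2k - 2 logL, k = 1 for all
three):

- ``zeta_powerlaw``   P(x) = x^(-alpha) / zeta(alpha),  alpha > 1
- ``logseries``       P(x) = -p^x / (x ln(1-p)),        0 < p < 1
- ``geometric``       P(x) = (1-p)^(x-1) p,             0 < p < 1

The zeta (discrete Pareto) model captures the heavy-tailed degree structure
typical of regulatory networks, where a few nodes concentrate most of the
interactions; the log-series and geometric models are the classical
lighter-tailed alternatives from the species-abundance literature.  A lower
AIC wins; when two datasets select the same model their distributions are
taken as similar in shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

MODELS = ("zeta_powerlaw", "logseries", "geometric")

_REL_TOL = 1e-8  # relative tolerance of the 1-D optimizations


class FitError(ValueError):
    """Raised when a model cannot be fitted on the given data."""


@dataclass(frozen=True)
class ModelFit:
    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int


@dataclass
class SelectionTable:
    fits: list[ModelFit]          # sorted by AIC ascending
    best: str
    delta_aic: dict[str, float]
    failures: dict[str, str] = field(default_factory=dict)

    def as_records(self) -> list[dict]:
        return [
            {
                "model": f.model,
                **{f"param_{k}": v for k, v in f.params.items()},
                "loglik": f.loglik,
                "aic": f.aic,
                "delta_aic": self.delta_aic[f.model],
                "n": f.n,
            }
            for f in self.fits
        ]


def aic_of(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * loglik


def _validate(degrees) -> np.ndarray:
    x = np.asarray(degrees, dtype=float)
    if x.size < 10:
        raise FitError(f"need at least 10 observations, got {x.size}")
    if np.any(x < 1) or np.any(x != np.floor(x)):
        raise FitError("degrees must be integers >= 1")
    return x


def _fit_zeta(x: np.ndarray) -> tuple[dict[str, float], float]:
    if np.all(x == 1):
        raise FitError("all degrees equal 1: zeta exponent diverges")
    slx = float(np.sum(np.log(x)))
    n = x.size

    def nll(alpha: float) -> float:
        return alpha * slx + n * np.log(special.zeta(alpha, 1.0))

    res = optimize.minimize_scalar(
        nll, bounds=(1.0 + 1e-9, 60.0), method="bounded",
        options={"xatol": _REL_TOL},
    )
    alpha = float(res.x)
    return {"alpha": alpha}, -float(res.fun)


def _fit_logseries(x: np.ndarray) -> tuple[dict[str, float], float]:
    mean = float(np.mean(x))
    if mean <= 1.0:
        raise FitError("all degrees equal 1: log-series p at boundary 0")

    # MLE solves  mean = -p / ((1-p) ln(1-p))
    def gap(p: float) -> float:
        return -p / ((1.0 - p) * np.log1p(-p)) - mean

    p = float(optimize.brentq(gap, 1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=1e-13))
    n = x.size
    loglik = float(
        np.sum(x) * np.log(p) - np.sum(np.log(x)) - n * np.log(-np.log1p(-p))
    )
    return {"p": p}, loglik


def _fit_geometric(x: np.ndarray) -> tuple[dict[str, float], float]:
    mean = float(np.mean(x))
    if mean <= 1.0:
        raise FitError("all degrees equal 1: geometric p at boundary 1")
    p = 1.0 / mean  # closed-form MLE, n / sum(x)
    n = x.size
    loglik = float(n * np.log(p) + (np.sum(x) - n) * np.log1p(-p))
    return {"p": p}, loglik


_FITTERS = {
    "zeta_powerlaw": _fit_zeta,
    "logseries": _fit_logseries,
    "geometric": _fit_geometric,
}


def model_pmf(model: str, params: dict[str, float], x) -> np.ndarray:
    """Probability mass of a fitted model on integer support x >= 1."""
    x = np.asarray(x, dtype=float)
    if model == "zeta_powerlaw":
        a = params["alpha"]
        return x ** (-a) / special.zeta(a, 1.0)
    if model == "logseries":
        p = params["p"]
        return -(p ** x) / (x * np.log1p(-p))
    if model == "geometric":
        p = params["p"]
        return (1.0 - p) ** (x - 1.0) * p
    raise ValueError(f"unknown model {model!r}")


def fit_model(degrees, model: str) -> ModelFit:
    """Fit one abundance model by maximum likelihood.

    Raises :class:`FitError` on degenerate data (all degrees 1, the boundary
    of every model's parameter space) or fewer than 10 observations.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    x = _validate(degrees)
    params, loglik = _FITTERS[model](x)
    return ModelFit(model=model, params=params, loglik=loglik,
                    aic=aic_of(loglik, k=1), n=x.size)


def select_model(degrees, model_set=MODELS) -> SelectionTable:
    """Fit every candidate model and rank by AIC.

    Unfittable models are recorded in ``failures`` rather than aborting.
    Near-ties (|dAIC| < 1e-9) break toward fewer parameters, then model name.
    """
    model_set = list(model_set)
    if not model_set:
        raise ValueError("model_set is empty")
    fits: list[ModelFit] = []
    failures: dict[str, str] = {}
    for m in model_set:
        try:
            fits.append(fit_model(degrees, m))
        except FitError as exc:
            failures[m] = str(exc)
    if not fits:
        raise FitError(f"no model could be fitted: {failures}")
    fits.sort(key=lambda f: (round(f.aic / 1e-9) * 1e-9, len(f.params), f.model))
    best = fits[0].model
    amin = fits[0].aic
    delta = {f.model: f.aic - amin for f in fits}
    return SelectionTable(fits=fits, best=best, delta_aic=delta, failures=failures)


def compare_groups(degrees_a, degrees_b, model_set=MODELS):
    """AIC model selection on two datasets plus a same-best-model verdict.

    Used to compare the degree distribution of transcription factors against
    the remaining mRNAs: the caller removes zero-degree TFs and subtracts the
    TF set from the mRNA set before calling, so the groups are disjoint.
    """
    ta = select_model(degrees_a, model_set)
    tb = select_model(degrees_b, model_set)
    return ta, tb, ta.best == tb.best


# ---------------------------------------------------------------------------
# simulation (inverse-CDF on a truncated mass table; used for tests/synthesis)

def sample_degrees(model: str, params: dict[str, float], n: int, seed,
                   d_max: int = 100_000) -> np.ndarray:
    """Draw degree observations from a fitted model, truncated at d_max."""
    rng = np.random.default_rng(seed)
    if model == "geometric":
        return rng.geometric(params["p"], size=n)
    if model == "logseries":
        return stats.logser.rvs(params["p"], size=n, random_state=rng)
    if model == "zeta_powerlaw":
        support = np.arange(1, d_max + 1, dtype=float)
        pmf = support ** (-params["alpha"])
        cdf = np.cumsum(pmf)
        cdf /= cdf[-1]
        u = rng.random(n)
        return np.searchsorted(cdf, u) + 1
    raise ValueError(f"unknown model {model!r}")
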