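"""Validation of genomic predictions on a masked set of animals.

Reliability is measured as the squared Pearson correlation between masked
yield deviations and predicted genomic values; inflation bias as the OLS
regression coefficient of the yield deviations on the predictions (slope 1 =
unbiased, < 1 = over-dispersed predictions).  Methods are compared by a
paired bootstrap over validation animals: a difference in reliability is
called significant when one method's correlation exceeds the other's in more
than 97.5% (or fewer than 2.5%) of resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

logger = logging.getLogger("gwablup")


def _check_pair(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if y.shape != g.shape or y.size < 3:
        raise ValidationError("need two aligned vectors of length >= 3")
    return y, g


def reliability(y_v: np.ndarray, g_hat: np.ndarray) -> float:
    """Squared Pearson correlation between masked phenotypes and predictions."""
    y, g = _check_pair(y_v, g_hat)
    if np.var(y) == 0 or np.var(g) == 0:
        raise ValidationError("reliability undefined for zero-variance input")
    r = np.corrcoef(y, g)[0, 1]
    return float(r * r)


def inflation_slope(y_v: np.ndarray, g_hat: np.ndarray) -> float:
    """OLS slope of the yield deviations on the predictions."""
    y, g = _check_pair(y_v, g_hat)
    vg = np.var(g)
    if vg == 0:
        raise ValidationError("inflation slope undefined for constant predictions")
    return float(np.cov(y, g, ddof=1)[0, 1] / np.var(g, ddof=1))


def relative_reliability(reliability: float, yd_reliability: float) -> float:
    """Prediction reliability expressed relative to the reliability of the
    yield deviations themselves, rounded to 2 decimals for reporting."""
    if not (yd_reliability > 0):
        raise ValidationError("yd_reliability must be positive")
    return round(reliability / yd_reliability, 2)


def bootstrap_compare(
    y_v: np.ndarray,
    g_hat_k: np.ndarray,
    g_hat_l: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    indices: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Paired bootstrap comparison of two methods' validation correlations.

    Resamples validation animals with replacement (jointly for y and both
    prediction vectors), scores the fraction of resamples in which
    ``cor(y, ĝ_k) > cor(y, ĝ_l)`` (ties count as not-greater), and flags
    significance when that fraction exceeds 0.975 (k better) or falls below
    0.025 (l better).  ``indices`` allows sharing one set of resampled
    indices across many comparisons (a paired design).
    """
    y, gk = _check_pair(y_v, g_hat_k)
    _, gl = _check_pair(y_v, g_hat_l)
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    n = y.size
    if indices is None:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        indices = rng.integers(0, n, size=(n_boot, n))
        # redraw degenerate resamples (constant y: correlation undefined)
        for attempt in range(100):
            bad = np.flatnonzero(np.ptp(y[indices], axis=1) == 0)
            if bad.size == 0:
                break
            logger.info("redrawing %d degenerate bootstrap resample(s)", bad.size)
            indices[bad] = rng.integers(0, n, size=(bad.size, n))

    yb = y[indices]
    yb = yb - yb.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.einsum("bi,bi->b", yb, yb))

    def _cor(g: np.ndarray) -> np.ndarray:
        gb = g[indices]
        gb = gb - gb.mean(axis=1, keepdims=True)
        sg = np.sqrt(np.einsum("bi,bi->b", gb, gb))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.einsum("bi,bi->b", yb, gb) / (sy * sg)

    ck, cl = _cor(gk), _cor(gl)
    ck = np.nan_to_num(ck, nan=-np.inf)
    cl = np.nan_to_num(cl, nan=-np.inf)
    frac = float(np.mean(ck > cl))
    frac_l = float(np.mean(cl > ck))  # ties favour neither method
    return frac, bool(frac > 0.975 or frac_l > 0.975)


@dataclass
class ValidationReport:
    """Per-trait reliabilities and slopes for several prediction methods,
    with paired bootstrap comparisons between all method pairs."""

    trait_names: list[str]
    methods: list[str]
    reliabilities: np.ndarray  # (n_methods, T)
    slopes: np.ndarray         # (n_methods, T)
    n_validation: int
    comparisons: pd.DataFrame  # method_k, method_l, trait, win_fraction, significant

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, name in enumerate(self.methods):
            for t, trait in enumerate(self.trait_names):
                rows.append({
                    "method": name, "trait": trait,
                    "reliability": self.reliabilities[m, t],
                    "slope": self.slopes[m, t],
                })
        return pd.DataFrame(rows)


def compare_methods(
    y_v: np.ndarray,
    predictions: dict[str, np.ndarray],
    trait_names: list[str],
    n_boot: int = 10000,
    seed: int = 0,
) -> ValidationReport:
    """Validate several methods' multitrait predictions on one masked set.

    One set of bootstrap indices is drawn and shared across every trait and
    method pair, coupling the comparisons as in a paired design.
    """
    methods = list(predictions)
    y_v = np.atleast_2d(np.asarray(y_v, dtype=float))
    n_v, T = y_v.shape
    rel = np.empty((len(methods), T))
    slp = np.empty((len(methods), T))
    for m, name in enumerate(methods):
        g = np.atleast_2d(np.asarray(predictions[name], dtype=float))
        for t in range(T):
            rel[m, t] = reliability(y_v[:, t], g[:, t])
            slp[m, t] = inflation_slope(y_v[:, t], g[:, t])
    rng = np.random.default_rng(seed)
    indices = rng.integers(0, n_v, size=(n_boot, n_v))
    rows = []
    for i, mk in enumerate(methods):
        for ml in methods[i + 1:]:
            for t, trait in enumerate(trait_names):
                frac, sig = bootstrap_compare(
                    y_v[:, t], predictions[mk][:, t], predictions[ml][:, t],
                    n_boot=n_boot, indices=indices,
                )
                rows.append({"method_k": mk, "method_l": ml, "trait": trait,
                             "win_fraction": frac, "significant": sig})
    comparisons = pd.DataFrame(
        rows, columns=["method_k", "method_l", "trait", "win_fraction",
                       "significant"]
    )
    return ValidationReport(list(trait_names), methods, rel, slp, n_v, comparisons)
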