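"""Receptor-status assignment from expression via two-component mixtures.

Tumor ER/PR/HER2 status is inferred by fitting each marker gene's log2(x+1)
expression with a two-component Gaussian mixture (equal-variance "E" or
variable-variance "V"), calling a sample positive when the posterior of the
higher-mean component exceeds a cutoff, and selecting the E/V combination
across the three markers that best matches the available IHC labels. A tumor
is triple-negative (TNBC) exactly when all three markers are called negative.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

log = logging.getLogger("tnbc_targets")

#: Relative variance floor: components may not shrink below this fraction of
#: the sample variance, which keeps EM away from singular solutions on ties.
VAR_FLOOR_FRAC = 1e-4

DEFAULT_MARKERS = ("ESR1", "PGR", "ERBB2")
_IHC_FOR_MARKER = {"ESR1": "ihc_er", "PGR": "ihc_pr", "ERBB2": "ihc_her2"}


class FitError(ValueError):
    """Raised for degenerate inputs the mixture model cannot be fit on."""


@dataclass
class MarkerFit:
    """Parameters of a two-component Gaussian mixture for one marker.

    Component 2 is always the higher-mean ("positive") component; under mode
    "E" the two variances are tied.
    """

    marker: str
    mode: str
    weights: tuple[float, float]
    means: tuple[float, float]
    variances: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        assert self.mode in ("E", "V")
        assert self.means[0] < self.means[1]
        assert abs(sum(self.weights) - 1.0) < 1e-9


def _em_once(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    mode: str,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = x.size
    loglik = -np.inf
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities of each component
        logcomp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        lognorm = logsumexp(logcomp, axis=1)
        new_loglik = float(lognorm.sum())
        resp = np.exp(logcomp - lognorm[:, None])
        trajectory.append(new_loglik)
        if math.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sq = (x[:, None] - mu[None, :]) ** 2
        if mode == "E":
            common = float((resp * sq).sum() / n)
            var = np.full(2, max(common, var_floor))
        else:
            var = np.maximum((resp * sq).sum(axis=0) / nk, var_floor)
    return w, mu, var, loglik, it, converged, trajectory


def fit_two_component(
    values: Sequence[float] | np.ndarray,
    mode: str = "E",
    seed: int = 0,
    *,
    marker: str = "marker",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    return_trajectory: bool = False,
):
    """Fit a two-component Gaussian mixture to log2(x+1) marker expression.

    Initialization splits the sorted data at the median (first restart) and
    at seeded jittered quantiles (remaining restarts), taking component
    moments from the two halves; the restart with the best final
    log-likelihood wins. EM iterates until the log-likelihood changes by
    less than ``tol`` or ``max_iter`` is reached.
    """
    if mode not in ("E", "V"):
        raise ValueError(f"mode must be 'E' or 'V', got {mode!r}")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need at least 10 finite values to fit a mixture, got {x.size}")
    sample_var = float(np.var(x))
    if sample_var == 0.0:
        raise FitError("degenerate input: all values are equal")
    var_floor = VAR_FLOOR_FRAC * sample_var
    rng = np.random.default_rng(seed)
    xs = np.sort(x)
    best = None
    best_traj: list[float] = []
    for restart in range(n_restarts):
        q = 0.5 if restart == 0 else 0.5 + rng.uniform(-0.2, 0.2)
        split = int(np.clip(round(q * x.size), 2, x.size - 2))
        lo, hi = xs[:split], xs[split:]
        w0 = np.array([lo.size / x.size, hi.size / x.size])
        mu0 = np.array([lo.mean(), hi.mean()])
        if mu0[0] == mu0[1]:
            mu0 = mu0 + np.array([-0.5, 0.5]) * math.sqrt(sample_var)
        if mode == "E":
            pooled = max((lo.var() * lo.size + hi.var() * hi.size) / x.size, var_floor)
            var0 = np.full(2, pooled)
        else:
            var0 = np.maximum(np.array([lo.var(), hi.var()]), var_floor)
        result = _em_once(x, w0, mu0, var0, mode, var_floor, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
            best_traj = result[6]
    w, mu, var, loglik, n_iter, converged, _ = best
    if mu[0] > mu[1]:  # relabel so component 2 is the positive one
        w, mu, var = w[::-1], mu[::-1], var[::-1]
    fit = MarkerFit(
        marker=marker,
        mode=mode,
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        variances=(float(var[0]), float(var[1])),
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
    )
    if return_trajectory:
        return fit, best_traj
    return fit


def em_trajectory(
    values,
    mode: str,
    weights,
    means,
    variances,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[float]:
    """Run EM from an explicit starting point and return the per-iteration
    log-likelihood sequence (useful for convergence audits)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    sample_var = float(np.var(x))
    if sample_var == 0.0:
        raise FitError("degenerate input: all values are equal")
    var_floor = VAR_FLOOR_FRAC * sample_var
    _, _, _, _, _, _, trajectory = _em_once(
        x,
        np.asarray(weights, dtype=float),
        np.asarray(means, dtype=float),
        np.maximum(np.asarray(variances, dtype=float), var_floor),
        mode,
        var_floor,
        tol,
        max_iter,
    )
    return trajectory


def posterior_positive(fit: MarkerFit, values) -> np.ndarray | float:
    """Bayes posterior that each value belongs to the higher-mean component."""
    x = np.asarray(values, dtype=float)
    logcomp = np.stack(
        [
            math.log(fit.weights[k])
            - 0.5 * math.log(2.0 * math.pi * fit.variances[k])
            - 0.5 * (x - fit.means[k]) ** 2 / fit.variances[k]
            for k in (0, 1)
        ],
        axis=-1,
    )
    post = np.exp(logcomp[..., 1] - logsumexp(logcomp, axis=-1))
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(post)
    return post


def fit_marker_models(
    values: pd.DataFrame,
    markers: Sequence[str] = DEFAULT_MARKERS,
    seed: int = 0,
) -> dict[str, dict[str, MarkerFit]]:
    """Fit both the E and V mixture for every marker gene.

    ``values`` is samples x markers on the log2(x+1) scale.
    """
    fits: dict[str, dict[str, MarkerFit]] = {}
    for offset, marker in enumerate(markers):
        if marker not in values.columns:
            raise FitError(f"marker {marker!r} absent from the expression table")
        fits[marker] = {
            mode: fit_two_component(
                values[marker].to_numpy(), mode=mode, seed=seed + offset, marker=marker
            )
            for mode in ("E", "V")
        }
    return fits


def _calls(fit: MarkerFit, values: np.ndarray, cutoff: float) -> np.ndarray:
    # strict inequality: a posterior exactly at the cutoff is called negative
    return posterior_positive(fit, values) > cutoff


def concordance(
    combo: Mapping[str, str],
    fits: Mapping[str, Mapping[str, MarkerFit]],
    values: pd.DataFrame,
    ihc: pd.DataFrame,
    posterior_cutoff: float = 0.5,
) -> tuple[float, int]:
    """Pooled agreement between mixture calls and IHC labels.

    The fraction is computed over all non-missing (sample, marker) pairs
    jointly, so every marker contributes in proportion to its labelled
    samples. Returns ``(fraction, n_pairs)``.
    """
    matches = 0
    total = 0
    for marker, mode in combo.items():
        labels = ihc[_IHC_FOR_MARKER[marker]]
        known = labels != "missing"
        if not known.any():
            continue
        calls = _calls(fits[marker][mode], values.loc[known.to_numpy(), marker].to_numpy(), posterior_cutoff)
        observed = (labels[known] == "pos").to_numpy()
        matches += int((calls == observed).sum())
        total += int(known.sum())
    return (matches / total if total else float("nan")), total


def select_model_combination(
    fits: Mapping[str, Mapping[str, MarkerFit]],
    values: pd.DataFrame,
    ihc: pd.DataFrame,
    posterior_cutoff: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Choose equal- vs variable-variance per marker by IHC concordance.

    All 2^3 E/V combinations are evaluated jointly; the one with the highest
    pooled concordance wins. Ties are broken toward more equal-variance
    modes, then lexicographically (E before V) in marker order. With no IHC
    labels at all the equal-variance model is used for every marker, with a
    logged warning.
    """
    markers = list(fits)
    report_rows = []
    any_ihc = any((ihc[_IHC_FOR_MARKER[m]] != "missing").any() for m in markers)
    if not any_ihc:
        log.warning("no IHC labels available; defaulting every marker to equal variance (E)")
        return {m: "E" for m in markers}, pd.DataFrame(
            [{"combination": "".join("E" for _ in markers), "concordance": float("nan"), "n_pairs": 0}]
        )
    best_combo = None
    best_key = None
    for modes in itertools.product("EV", repeat=len(markers)):
        combo = dict(zip(markers, modes))
        frac, n_pairs = concordance(combo, fits, values, ihc, posterior_cutoff)
        report_rows.append({"combination": "".join(modes), "concordance": frac, "n_pairs": n_pairs})
        key = (-frac, sum(m == "V" for m in modes), modes)
        if best_key is None or key < best_key:
            best_key = key
            best_combo = combo
    report = pd.DataFrame(report_rows)
    log.info(
        "selected mixture combination %s (concordance %.4f)",
        "".join(best_combo.values()),
        -best_key[0],
    )
    return best_combo, report


def assign_markers(
    chosen: Mapping[str, MarkerFit],
    values: pd.DataFrame,
    posterior_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Per-sample posteriors and pos/neg calls for each marker.

    Returns a frame indexed by sample with ``posterior_<marker>`` and
    ``call_<marker>`` columns.
    """
    out = pd.DataFrame(index=values.index)
    for marker, fit in chosen.items():
        post = posterior_positive(fit, values[marker].to_numpy())
        out[f"posterior_{marker}"] = post
        out[f"call_{marker}"] = np.where(post > posterior_cutoff, "pos", "neg")
    return out


def assign_tnbc(assignments: pd.DataFrame, markers: Sequence[str] = DEFAULT_MARKERS) -> pd.Series:
    """TNBC status: triple-negative exactly when all marker calls are negative."""
    all_neg = np.ones(len(assignments), dtype=bool)
    for marker in markers:
        all_neg &= (assignments[f"call_{marker}"] == "neg").to_numpy()
    return pd.Series(np.where(all_neg, "TNBC", "non-TNBC"), index=assignments.index, name="tnbc_status")
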