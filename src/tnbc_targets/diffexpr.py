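"""Differential expression/abundance engine and category enrichment.

One engine serves every comparison in the pipeline: an empirical-Bayes
moderated two-sample t-statistic computed on log2-scale values. Per-gene
residual variances s_g^2 (d = nA + nB - 2 degrees of freedom) are shrunk
toward a prior (d0, s0^2) estimated by moment matching on log s^2, giving
the posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the statistic t_g = log2fc_g / (s~_g * sqrt(1/nA + 1/nB)) with d0 + d
degrees of freedom. The fold-change sign convention is group A minus group
B (the pipeline always passes TNBC as group A, so positive means higher in
TNBC). Multiple testing uses step-up Benjamini-Hochberg; a gene is "up"
when log2fc >= fc_up_threshold and fdr <= fdr_threshold (both inclusive),
and symmetrically "down". Category enrichment uses Wallenius' noncentral
hypergeometric distribution, which reduces to the central hypergeometric
tail when all gene weights are equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import PipelineConfig

log = logging.getLogger("tnbc_targets")


@dataclass
class EBayesPrior:
    """Empirical-Bayes prior on gene-level variances: d0 degrees of freedom
    worth of confidence in a prior variance s0^2. ``d0 = inf`` means total
    shrinkage to s0^2; ``d0 = 0`` recovers the ordinary pooled t-test."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError(f"d0 must be >= 0 (inf allowed), got {self.d0}")
        if not (self.s0_sq > 0) and not (self.d0 == 0):
            raise ValueError(f"s0_sq must be positive, got {self.s0_sq}")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def estimate_ebayes_prior(s2: np.ndarray, d: float) -> EBayesPrior:
    """Moment-match (d0, s0^2) from observed residual variances.

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0), the log variances
    have closed-form mean and variance in terms of digamma/trigamma
    functions; matching the empirical moments of log s^2 and inverting the
    trigamma by Newton iteration yields the prior. When the spread of
    log s^2 is no larger than the sampling noise alone, d0 is infinite and
    every gene shares s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need at least two positive variances to estimate a prior")
    if positive.size < s2.size:
        log.warning(
            "excluding %d zero-variance genes from prior estimation", s2.size - positive.size
        )
    z = np.log(positive)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: variances are homogeneous,
        # so the common value is simply their arithmetic mean
        d0 = math.inf
        s0_sq = float(positive.mean())
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def _group_indices(samples: pd.Index, groups: Mapping[str, str] | pd.Series, a: str, b: str):
    labels = pd.Series(groups)
    labels = labels.reindex(samples)
    ia = np.flatnonzero((labels == a).to_numpy())
    ib = np.flatnonzero((labels == b).to_numpy())
    return ia, ib


def moderated_t_test(
    frame: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test on a log-scale genes-by-samples frame.

    ``groups`` maps sample id to a group label; samples labelled neither
    ``group_a`` nor ``group_b`` are ignored. Returns a frame indexed by gene
    with ``log2fc`` (A minus B), ``stat``, ``p`` and BH-adjusted ``fdr``.
    """
    ia, ib = _group_indices(frame.columns, groups, group_a, group_b)
    na, nb = ia.size, ib.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 samples, got {group_a}: {na}, {group_b}: {nb}")
    x = frame.to_numpy(dtype=float)
    xa, xb = x[:, ia], x[:, ib]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    log2fc = ma - mb
    d = na + nb - 2
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    if prior is None:
        prior = estimate_ebayes_prior(s2, d)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    # cap at the pooled residual df across genes: with many genes this is
    # numerically a normal tail, but keeps a proper t reference distribution
    df_total = min(df_total, d * len(frame))
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(stat), df_total)
    result = pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "p": p, "fdr": bh_adjust(p)}, index=frame.index
    )
    result.index.name = "gene_id"
    return result


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, returned in input order.

    q_i = min_{j >= i} (m * p_(j) / j), clipped at 1, where p_(j) are the
    ascending order statistics.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_de(results: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Attach up/down/ns status using the fold-change and FDR gates.

    Both gates are inclusive: log2fc exactly at the threshold and fdr
    exactly at the cutoff still qualify.
    """
    cfg = cfg or PipelineConfig()
    out = results.copy()
    passes_fdr = out["fdr"] <= cfg.fdr_threshold
    up = (out["log2fc"] >= cfg.fc_up_threshold) & passes_fdr
    down = (out["log2fc"] <= cfg.fc_down_threshold) & passes_fdr
    out["status"] = np.select([up, down], ["up", "down"], default="ns")
    log.info("DE classification: %d up, %d down of %d genes", up.sum(), down.sum(), len(out))
    return out


def wallenius_enrichment(
    de_set: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    weights: Mapping[str, float] | pd.Series | None = None,
) -> float:
    """Upper-tail enrichment p-value under Wallenius' noncentral model.

    Tests whether the DE set contains at least the observed number of
    category genes when genes are drawn without replacement with odds
    omega = (mean weight inside the category) / (mean weight outside).
    Unit weights reduce exactly to the central hypergeometric tail.
    """
    universe = sorted(set(universe))
    cat = set(category)
    de = set(de_set)
    if not cat <= set(universe):
        raise ValueError("category must be a subset of the universe")
    if not de <= set(universe):
        raise ValueError("DE set must be a subset of the universe")
    total = len(universe)
    n_cat = len(cat)
    n_draws = len(de)
    k = len(de & cat)
    if n_cat == 0 or n_draws == 0:
        log.warning("empty category or DE set; enrichment p-value set to 1")
        return 1.0
    if weights is None:
        omega = 1.0
    else:
        w = pd.Series(weights).reindex(universe)
        if w.isna().any() or (w <= 0).any():
            raise ValueError("weights must be positive for every gene in the universe")
        inside = w[w.index.isin(cat)]
        outside = w[~w.index.isin(cat)]
        omega = 1.0 if outside.empty else float(inside.mean() / outside.mean())
    if np.isclose(omega, 1.0):
        return float(stats.hypergeom.sf(k - 1, total, n_cat, n_draws))
    return float(stats.nchypergeom_wallenius.sf(k - 1, total, n_cat, n_draws, omega))
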