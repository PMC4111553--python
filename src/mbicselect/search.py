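"""Fast stepwise search (FSS) minimizing mBIC-type criteria, and the
three-round search schedule.

FSS cycles three moves starting from an initial model:

* directed forward — walk a pre-ranked candidate group P1 and add the first
  SNP whose inclusion strictly lowers the criterion;
* exchange — for each model SNP, try swapping it with ranked candidates (P2)
  that lie within an index window on the same chromosome, applying the best
  improving swap;
* extended backward — greedily drop the least explanatory SNP up to a fixed
  depth, keeping the best model seen along the way.

The full schedule runs FSS three times: first with a marginal
(Cochran-Armitage) candidate ordering under the milder criterion mBIC_E,
then with conditional score-test orderings under mBIC_E and finally under
the target criterion mBIC2, whose minimizer has FDR-controlled selections.
Every candidate model is evaluated by an exact Firth refit (cached and
warm-started); the search is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .assoc import SnpOrdering, order_snps
from .criteria import CriterionConfig
from .datasets import GenotypeDataset
from .firth import ModelFit, firth_fit

__all__ = [
    "SearchConfig",
    "directed_forward",
    "exchange_step",
    "backward_step",
    "fss",
    "full_search",
    "MbicGwasSelector",
]

# minimal strict decrease for accepting a move; well above fit tolerance noise
_EPS = 1e-7


@dataclass
class SearchConfig:
    """Tunables of the stepwise search.

    ``p1``/``p2`` are the forward- and exchange-candidate group sizes
    (``p2 = None`` means min(p, 5000)); ``window`` is the number of
    neighboring SNPs considered on each side in exchange steps; the exchange
    group is halved once the model grows past ``p2_shrink_threshold`` (a
    runtime guard).  ``criterion`` carries both the mBIC2 constant ``c`` and
    the milder-round prior model size ``E``.
    """

    p1: int = 100
    p2: Optional[int] = None
    window: int = 49
    max_backward_depth: int = 3
    p2_shrink_threshold: int = 25
    max_sweeps: int = 100
    criterion: CriterionConfig = field(default_factory=CriterionConfig)
    fit_tol: float = 1e-6
    fit_max_iter: int = 50

    def __post_init__(self) -> None:
        if self.p1 < 1:
            raise ValueError("p1 must be >= 1")
        if self.p2 is not None and self.p2 < self.p1:
            raise ValueError("p2 must be >= p1")
        if self.window < 0 or self.max_backward_depth < 1:
            raise ValueError("window must be >= 0 and max_backward_depth >= 1")

    def resolved_p2(self, p: int) -> int:
        return min(p, 5000) if self.p2 is None else min(self.p2, p)


class _SearchState:
    """Per-dataset fit cache shared across rounds (fits are criterion-free)."""

    def __init__(self, ds: GenotypeDataset, cfg: SearchConfig):
        self.ds = ds
        self.cfg = cfg
        self.chrom = ds.snps["chrom"].to_numpy()
        self._cache: dict = {}

    def fit(self, indices, warm_from: Optional[ModelFit] = None) -> ModelFit:
        key = frozenset(int(i) for i in indices)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        idx = tuple(sorted(key))
        beta_start = None
        if warm_from is not None:
            old = dict(zip(warm_from.snp_indices, warm_from.beta[1:]))
            beta_start = np.concatenate(
                [[warm_from.beta[0]], [old.get(j, 0.0) for j in idx]]
            )
        fit = firth_fit(
            self.ds, idx, tol=self.cfg.fit_tol, max_iter=self.cfg.fit_max_iter,
            beta_start=beta_start,
        )
        self._cache[key] = fit
        return fit

    def crit(self, fit: ModelFit, ccfg: CriterionConfig) -> float:
        return ccfg.evaluate(ccfg.loglik_of(fit), self.ds.n, self.ds.p, fit.k)


def _state(ds, cfg, state) -> _SearchState:
    return state if state is not None else _SearchState(ds, cfg)


def directed_forward(
    ds: GenotypeDataset,
    fit: ModelFit,
    ordering: SnpOrdering,
    cfg: SearchConfig,
    criterion: Optional[CriterionConfig] = None,
    state: Optional[_SearchState] = None,
) -> ModelFit:
    """Add the first top-``p1`` candidate whose inclusion lowers the criterion."""
    st = _state(ds, cfg, state)
    ccfg = criterion or cfg.criterion
    current = st.crit(fit, ccfg)
    in_model = set(fit.snp_indices)
    for snp in ordering.order[: cfg.p1]:
        snp = int(snp)
        if snp in in_model:
            continue
        cand = st.fit(fit.snp_indices + (snp,), warm_from=fit)
        if st.crit(cand, ccfg) < current - _EPS:
            return cand
    return fit


def _exchange_candidates(st: _SearchState, snp: int, p2_set, in_model) -> list:
    w = st.cfg.window
    lo, hi = max(0, snp - w), min(st.ds.p - 1, snp + w)
    same_chrom = st.chrom[snp]
    return [
        j
        for j in range(lo, hi + 1)
        if j != snp and j in p2_set and j not in in_model and st.chrom[j] == same_chrom
    ]


def exchange_step(
    ds: GenotypeDataset,
    fit: ModelFit,
    cfg: SearchConfig,
    criterion: Optional[CriterionConfig] = None,
    state: Optional[_SearchState] = None,
    p2_set=None,
) -> ModelFit:
    """One pass of best-improving swaps of model SNPs with windowed candidates."""
    st = _state(ds, cfg, state)
    ccfg = criterion or cfg.criterion
    if p2_set is None:
        ordering = order_snps(ds, fit, "marginal")
        p2_set = set(int(j) for j in ordering.order[: cfg.resolved_p2(ds.p)])
    current_fit = fit
    for snp in tuple(sorted(fit.snp_indices)):
        if snp not in current_fit.snp_indices:
            continue
        in_model = set(current_fit.snp_indices)
        current_val = st.crit(current_fit, ccfg)
        best_val, best_fit = current_val, None
        base = tuple(j for j in current_fit.snp_indices if j != snp)
        for alt in _exchange_candidates(st, snp, p2_set, in_model):
            cand = st.fit(base + (alt,), warm_from=current_fit)
            val = st.crit(cand, ccfg)
            if val < best_val - _EPS:
                best_val, best_fit = val, cand
        if best_fit is not None:
            current_fit = best_fit
    return current_fit


def backward_step(
    ds: GenotypeDataset,
    fit: ModelFit,
    cfg: SearchConfig,
    criterion: Optional[CriterionConfig] = None,
    state: Optional[_SearchState] = None,
) -> ModelFit:
    """Greedy elimination up to ``max_backward_depth``, keeping the best model seen.

    Deeper removals are explored even when the first removal worsens the
    criterion, which lets the search escape one-step local minima.
    """
    st = _state(ds, cfg, state)
    ccfg = criterion or cfg.criterion
    best_fit, best_val = fit, st.crit(fit, ccfg)
    current = fit
    for _ in range(cfg.max_backward_depth):
        if current.k == 0:
            break
        step_best = None
        step_val = np.inf
        for snp in sorted(current.snp_indices):
            cand = st.fit(
                tuple(j for j in current.snp_indices if j != snp), warm_from=current
            )
            val = st.crit(cand, ccfg)
            if val < step_val:
                step_val, step_best = val, cand
        current = step_best
        if step_val < best_val - _EPS:
            best_fit, best_val = current, step_val
    return best_fit


def fss(
    ds: GenotypeDataset,
    init: ModelFit,
    ordering_method: str = "marginal",
    cfg: Optional[SearchConfig] = None,
    criterion: Optional[CriterionConfig] = None,
    state: Optional[_SearchState] = None,
    trace: Optional[list] = None,
    round_label: str = "fss",
) -> ModelFit:
    """Fast stepwise search from ``init`` under the given criterion.

    The candidate ordering (excluding ``init``'s SNPs) is computed once per
    call; forward, exchange and backward steps then cycle until a full cycle
    brings no criterion improvement (or ``max_sweeps`` is hit).  The result
    never scores worse than ``init``.
    """
    cfg = cfg or SearchConfig()
    st = _state(ds, cfg, state)
    ccfg = criterion or cfg.criterion
    ordering = order_snps(ds, init, ordering_method)
    p2_full = list(int(j) for j in ordering.order[: cfg.resolved_p2(ds.p)])

    def log(sweep, step, fit):
        if trace is not None:
            trace.append(
                {
                    "round": round_label,
                    "sweep": sweep,
                    "step": step,
                    "model_size": fit.k,
                    "criterion": st.crit(fit, ccfg),
                }
            )

    current = init
    log(0, "init", current)
    for sweep in range(1, cfg.max_sweeps + 1):
        before = st.crit(current, ccfg)
        current = directed_forward(ds, current, ordering, cfg, ccfg, st)
        log(sweep, "forward", current)
        p2_eff = p2_full
        if current.k > cfg.p2_shrink_threshold:
            p2_eff = p2_full[: max(cfg.p1, len(p2_full) // 2)]
        current = exchange_step(ds, current, cfg, ccfg, st, p2_set=set(p2_eff))
        log(sweep, "exchange", current)
        current = backward_step(ds, current, cfg, ccfg, st)
        log(sweep, "backward", current)
        if not st.crit(current, ccfg) < before - _EPS:
            break
    return current


def full_search(
    ds: GenotypeDataset,
    cfg: Optional[SearchConfig] = None,
    return_trace: bool = False,
):
    """Three-round search: marginal/mBIC_E, conditional/mBIC_E, conditional/mBIC2.

    Returns the final :class:`ModelFit` (and the search trace as a DataFrame
    when ``return_trace`` is set).  The dataset must be QC'd and imputed.
    """
    cfg = cfg or SearchConfig()
    if np.isnan(ds.genotypes).any():
        raise ValueError("dataset contains missing genotypes; impute first")
    st = _SearchState(ds, cfg)
    milder = replace(cfg.criterion, name="mBIC_E")
    target = replace(cfg.criterion, name="mBIC2")
    trace: list = []
    null = st.fit(())
    m1 = fss(ds, null, "marginal", cfg, milder, st, trace, "1:CA/mBIC_E")
    m2 = fss(ds, m1, "conditional", cfg, milder, st, trace, "2:score/mBIC_E")
    m3 = fss(ds, m2, "conditional", cfg, target, st, trace, "3:score/mBIC2")
    if return_trace:
        return m3, pd.DataFrame(trace)
    return m3


class MbicGwasSelector(SelectorMixin, BaseEstimator):
    """SNP subset selection by minimizing mBIC2 with the three-round search.

    A scikit-learn feature selector: ``fit(X, y)`` on an additive 0/1/2
    genotype matrix and binary status, then ``transform`` keeps the selected
    columns.  When no SNP metadata is given, all columns are treated as one
    pseudo-chromosome in matrix order.

    Parameters mirror :class:`SearchConfig` and :class:`CriterionConfig`.

    Attributes
    ----------
    support_ : bool mask of selected columns
    snp_indices_ : tuple of selected column indices
    coef_, intercept_ : Firth-fitted coefficients of the selected model
    criterion_ : float, the final mBIC2 value
    model_fit_ : ModelFit
    trace_ : DataFrame, per-step search log
    """

    def __init__(
        self,
        c: float = 4.0,
        E: float = 60.0,
        p1: int = 100,
        p2: Optional[int] = None,
        window: int = 49,
        max_backward_depth: int = 3,
        p2_shrink_threshold: int = 25,
        max_sweeps: int = 100,
    ):
        self.c = c
        self.E = E
        self.p1 = p1
        self.p2 = p2
        self.window = window
        self.max_backward_depth = max_backward_depth
        self.p2_shrink_threshold = p2_shrink_threshold
        self.max_sweeps = max_sweeps

    def _search_config(self) -> SearchConfig:
        return SearchConfig(
            p1=self.p1,
            p2=self.p2,
            window=self.window,
            max_backward_depth=self.max_backward_depth,
            p2_shrink_threshold=self.p2_shrink_threshold,
            max_sweeps=self.max_sweeps,
            criterion=CriterionConfig(name="mBIC2", c=self.c, E=self.E),
        )

    def fit(self, X, y, snps: Optional[pd.DataFrame] = None):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must be binary case/control status")
        ybin = (y == classes[1]).astype(np.int8)
        if snps is None:
            p = X.shape[1]
            snps = pd.DataFrame(
                {
                    "snp_id": [f"snp{j}" for j in range(p)],
                    "chrom": "1",
                    "pos_bp": np.arange(1, p + 1),
                    "allele1": "A",
                    "allele2": "B",
                }
            )
        ds = GenotypeDataset(X, snps, ybin)
        cfg = self._search_config()
        fit, trace = full_search(ds, cfg, return_trace=True)
        self.model_fit_ = fit
        self.trace_ = trace
        self.snp_indices_ = fit.snp_indices
        self.support_ = np.isin(np.arange(X.shape[1]), fit.snp_indices)
        self.intercept_ = fit.beta[0]
        self.coef_ = fit.beta[1:]
        target = replace(cfg.criterion, name="mBIC2")
        self.criterion_ = target.evaluate(target.loglik_of(fit), ds.n, ds.p, fit.k)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
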