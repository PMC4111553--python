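"""Stepwise search: individual moves, FSS against an exhaustive oracle, and
the three-round schedule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mbicselect.criteria import CriterionConfig
from mbicselect.firth import firth_fit
from mbicselect.assoc import order_snps
from mbicselect.search import (
    MbicGwasSelector,
    SearchConfig,
    backward_step,
    directed_forward,
    exchange_step,
    fss,
    full_search,
)

from conftest import make_dataset


def planted_dataset(rng, n=400, p=12, causal=(3,), beta=2.0, maf=0.3):
    g = rng.binomial(2, maf, size=(n, p)).astype(float)
    eta = -beta * np.mean([g[:, c].mean() for c in causal]) * len(causal)
    eta = eta + beta * g[:, list(causal)].sum(axis=1)
    y = (rng.random(n) < expit(eta)).astype(int)
    y[:2] = [0, 1]
    return make_dataset(g, y)


def exhaustive_minimum(ds, ccfg, max_size):
    """Independent oracle: best criterion over all SNP subsets up to max_size."""
    best_val, best_set = np.inf, ()
    for k in range(max_size + 1):
        for subset in itertools.combinations(range(ds.p), k):
            fit = firth_fit(ds, subset)
            val = ccfg.evaluate(ccfg.loglik_of(fit), ds.n, ds.p, fit.k)
            if val < best_val - 1e-12:
                best_val, best_set = val, subset
    return best_val, best_set


@pytest.fixture
def tiny_cfg():
    return SearchConfig(p1=12, p2=12, window=49)


class TestMoves:
    def test_forward_on_empty_candidate_group_keeps_model(self, rng, tiny_cfg):
        ds = planted_dataset(rng)
        null = firth_fit(ds, ())
        from mbicselect.assoc import SnpOrdering

        out = directed_forward(
            ds, null, SnpOrdering(np.array([], dtype=int), np.array([])), tiny_cfg
        )
        assert out.snp_indices == ()

    def test_forward_adds_planted_snp_and_lowers_criterion(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(5,), beta=2.5)
        null = firth_fit(ds, ())
        ordering = order_snps(ds, null, "marginal")
        ccfg = tiny_cfg.criterion
        out = directed_forward(ds, null, ordering, tiny_cfg)
        assert 5 in out.snp_indices
        before = ccfg.evaluate(ccfg.loglik_of(null), ds.n, ds.p, 0)
        after = ccfg.evaluate(ccfg.loglik_of(out), ds.n, ds.p, out.k)
        assert after < before

    def test_exchange_replaces_proxy_with_causal_neighbor(self, rng, tiny_cfg):
        # SNP 4 is an LD proxy of causal SNP 5; model starts on the proxy
        n = 600
        latent = rng.standard_normal((n, 2))
        z_causal = latent[:, 0]
        z_proxy = 0.9 * z_causal + np.sqrt(1 - 0.81) * latent[:, 1]
        from scipy.stats import norm

        thresh = norm.ppf(0.4)
        g = rng.binomial(2, 0.3, size=(n, 12)).astype(float)
        g[:, 5] = (z_causal < thresh) + (rng.standard_normal(n) < thresh)
        g[:, 4] = (z_proxy < thresh) + (rng.standard_normal(n) < thresh)
        y = (rng.random(n) < expit(-0.5 + 1.5 * g[:, 5])).astype(int)
        ds = make_dataset(g, y)
        start = firth_fit(ds, (4,))
        out = exchange_step(ds, start, tiny_cfg)
        assert out.snp_indices == (5,)

    def test_exchange_never_raises_criterion(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(2, 7), beta=1.0)
        ccfg = tiny_cfg.criterion
        start = firth_fit(ds, (2, 3))
        out = exchange_step(ds, start, tiny_cfg)
        before = ccfg.evaluate(ccfg.loglik_of(start), ds.n, ds.p, start.k)
        after = ccfg.evaluate(ccfg.loglik_of(out), ds.n, ds.p, out.k)
        assert after <= before + 1e-9

    def test_backward_removes_noise_snp(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(3,), beta=2.5)
        bloated = firth_fit(ds, (3, 9))  # 9 is pure noise
        out = backward_step(ds, bloated, tiny_cfg)
        assert out.snp_indices == (3,)

    def test_backward_null_model_unchanged(self, rng, tiny_cfg):
        ds = planted_dataset(rng)
        null = firth_fit(ds, ())
        assert backward_step(ds, null, tiny_cfg).snp_indices == ()

    def test_backward_never_raises_criterion(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(1, 6), beta=1.5)
        ccfg = tiny_cfg.criterion
        start = firth_fit(ds, (1, 6, 10, 11))
        out = backward_step(ds, start, tiny_cfg)
        before = ccfg.evaluate(ccfg.loglik_of(start), ds.n, ds.p, start.k)
        after = ccfg.evaluate(ccfg.loglik_of(out), ds.n, ds.p, out.k)
        assert after <= before + 1e-9


class TestFss:
    def test_attains_exhaustive_minimum_on_tiny_instances(self, tiny_cfg):
        hits = 0
        trials = 50
        ccfg = CriterionConfig(name="mBIC2")
        for seed in range(trials):
            rng = np.random.default_rng(1000 + seed)
            k_causal = 1 + seed % 2
            causal = tuple(rng.choice(12, size=k_causal, replace=False))
            ds = planted_dataset(rng, causal=causal, beta=1.6)
            null = firth_fit(ds, ())
            found = fss(ds, null, "marginal", tiny_cfg, ccfg)
            found_val = ccfg.evaluate(ccfg.loglik_of(found), ds.n, ds.p, found.k)
            oracle_val, _ = exhaustive_minimum(ds, ccfg, max_size=3)
            if found_val <= oracle_val + 1e-6:
                hits += 1
        assert hits / trials >= 0.9

    def test_trace_strictly_decreasing_within_each_round(self, rng):
        ds = planted_dataset(rng, p=20, causal=(2, 11), beta=1.8)
        cfg = SearchConfig(p1=20, p2=20)
        _, trace = full_search(ds, cfg, return_trace=True)
        for _, sub in trace.groupby("round", sort=False):
            vals = sub["criterion"].to_numpy()
            changed = np.diff(vals) != 0
            assert (np.diff(vals)[changed] < 0).all()

    def test_idempotent_at_its_own_fixed_point(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(4,), beta=2.0)
        null = firth_fit(ds, ())
        ccfg = CriterionConfig(name="mBIC2")
        once = fss(ds, null, "marginal", tiny_cfg, ccfg)
        twice = fss(ds, once, "marginal", tiny_cfg, ccfg)
        assert once.snp_indices == twice.snp_indices

    def test_never_scores_worse_than_init(self, rng, tiny_cfg):
        ds = planted_dataset(rng, causal=(0,), beta=1.0)
        ccfg = CriterionConfig(name="mBIC2")
        init = firth_fit(ds, (6,))
        out = fss(ds, init, "conditional", tiny_cfg, ccfg)
        init_val = ccfg.evaluate(ccfg.loglik_of(init), ds.n, ds.p, init.k)
        out_val = ccfg.evaluate(ccfg.loglik_of(out), ds.n, ds.p, out.k)
        assert out_val <= init_val + 1e-9


class TestFullSearch:
    def test_planted_five_strong_snps_recovered(self, rng):
        n, p = 800, 60
        g = rng.binomial(2, 0.35, size=(n, p)).astype(float)
        causal = [5, 17, 29, 41, 53]
        eta = -2.5 * 0.7 * 5 + 2.5 * g[:, causal].sum(axis=1)
        y = (rng.random(n) < expit(eta)).astype(int)
        ds = make_dataset(g, y)
        fit = full_search(ds, SearchConfig(p1=60))
        selected = set(fit.snp_indices)
        assert set(causal) <= selected
        assert len(selected - set(causal)) <= 1

    def test_deterministic(self, rng):
        ds = planted_dataset(rng, p=15, causal=(8,), beta=2.0)
        cfg = SearchConfig(p1=15)
        a = full_search(ds, cfg)
        b = full_search(ds, cfg)
        assert a.snp_indices == b.snp_indices
        assert a.penalized_loglik == b.penalized_loglik

    def test_missing_genotypes_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(30, 3)).astype(float)
        g[0, 0] = np.nan
        ds = make_dataset(g, rng.integers(0, 2, size=30))
        with pytest.raises(ValueError, match="missing"):
            full_search(ds)


class TestSelectorEstimator:
    def test_fit_transform_and_support(self, rng):
        n, p = 500, 25
        g = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = (rng.random(n) < expit(-1.4 + 2.0 * g[:, 7])).astype(int)
        sel = MbicGwasSelector(p1=25)
        sel.fit(g, y)
        assert sel.support_[7]
        reduced = sel.transform(g)
        assert reduced.shape == (n, int(sel.support_.sum()))
        assert isinstance(sel.trace_, pd.DataFrame)
        assert np.isfinite(sel.criterion_)

    def test_composes_with_sklearn_pipeline(self, rng):
        from sklearn.pipeline import Pipeline

        from mbicselect.firth import FirthLogisticRegression

        n, p = 400, 15
        g = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = (rng.random(n) < expit(-1.0 + 1.8 * g[:, 2])).astype(int)
        pipe = Pipeline(
            [("select", MbicGwasSelector(p1=15)), ("clf", FirthLogisticRegression())]
        )
        pipe.fit(g, y)
        assert pipe.predict(g).shape == (n,)

    def test_rejects_nonbinary_phenotype(self, rng):
        g = rng.binomial(2, 0.3, size=(30, 3)).astype(float)
        with pytest.raises(ValueError):
            MbicGwasSelector().fit(g, np.arange(30))
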