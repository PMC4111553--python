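"""Model-selection criteria: mBIC2 and the milder mBIC_E.

For a model with ``k`` of ``p`` candidate SNPs fitted on ``n`` individuals,

    mBIC2  = -2 loglik + k log(n p^2 / c^2) - 2 log(k!)        (c = 4)
    mBIC_E = -2 loglik + k log(n p^2 / E^2)                    (E = 60)

where ``loglik`` is the Firth-penalized maximum log-likelihood.  Smaller is
better.  mBIC2 controls the FDR of selected SNPs at roughly the 10% level;
mBIC_E with a prior expected model size E > c penalizes each SNP less and is
used in early search rounds to avoid local minima ("mBIC_60").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class CriterionConfig:
    """Constants of the selection criteria.

    ``c`` enters mBIC2 (default 4); ``E`` is the prior expected model size of
    mBIC_E (default 60, hence "mBIC_60").  ``loglik_source`` says which
    maximized log-likelihood of the Firth fit feeds the criterion: ``"ml"``
    (the ordinary log-likelihood at the Firth-corrected estimate, default)
    or ``"penalized"`` (including the Jeffreys half-log-determinant).  The
    Jeffreys term grows by about ``log(n w sigma_x^2)/2`` per added SNP, a
    model-size-dependent reward that re-levels the FDR calibration of the
    penalty, so the criterion scores with the ordinary likelihood while the
    Firth penalty still stabilizes estimation.
    """

    name: str = "mBIC2"
    c: float = 4.0
    E: float = 60.0
    loglik_source: str = "ml"

    def __post_init__(self) -> None:
        if self.name not in ("mBIC2", "mBIC_E"):
            raise ValueError("name must be 'mBIC2' or 'mBIC_E'")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if self.loglik_source not in ("ml", "penalized"):
            raise ValueError("loglik_source must be 'ml' or 'penalized'")

    def loglik_of(self, fit) -> float:
        """The log-likelihood of a :class:`~mbicselect.firth.ModelFit` that
        this criterion scores with."""
        if self.loglik_source == "penalized":
            return fit.penalized_loglik
        ll = fit.loglik
        return fit.penalized_loglik if np.isnan(ll) else ll

    def evaluate(self, loglik: float, n: int, p: int, k: int) -> float:
        if self.name == "mBIC2":
            return mbic2(loglik, n, p, k, self)
        return mbic_e(loglik, n, p, k, self)


def _check_sizes(n: int, p: int, k: int) -> None:
    if n < 1 or p < 1 or k < 0:
        raise ValueError("require n >= 1, p >= 1, k >= 0")
    if k > p:
        raise ValueError(f"model size k={k} exceeds number of SNPs p={p}")


def mbic2(loglik: float, n: int, p: int, k: int, cfg: CriterionConfig = None) -> float:
    """mBIC2 value of a k-SNP model; smaller is better."""
    c = 4.0 if cfg is None else cfg.c
    _check_sizes(n, p, k)
    log_kfact = float(gammaln(k + 1))
    return -2.0 * loglik + k * np.log(n * p**2 / c**2) - 2.0 * log_kfact


def mbic_e(loglik: float, n: int, p: int, k: int, cfg: CriterionConfig = None) -> float:
    """mBIC with prior expected model size E (no k! term); smaller is better."""
    E = 60.0 if cfg is None else cfg.E
    _check_sizes(n, p, k)
    return -2.0 * loglik + k * np.log(n * p**2 / E**2)
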