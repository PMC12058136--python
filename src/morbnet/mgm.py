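"""Conditional-dependence network over binary diseases via nodewise L1 logistic regression.

All disease indicators are binary, so the general mixed graphical model
reduces to the Ising/logistic case and is implemented directly: one
L1-penalized logistic regression of each disease on all the others, with
a cross-validated (or extended-BIC) penalty per node, followed by AND-rule
aggregation of the two directed coefficients per pair into one undirected
signed edge. Because the data are {0,1}-coded, the aggregated weights
estimate the Ising couplings themselves.

Usage follows the model/results convention::

    model = DiseaseNetworkModel(cohort, MGMConfig(seed=7))
    res = model.fit()
    res.network            # PairwiseNetwork
    res.accuracy()         # per-disease classification accuracy
    res.summary()          # DataFrame: disease, lambda, support size, accuracy
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _solver
from ._solver import (
    l1_logistic,
    lambda_path,
    predict_proba,
    select_lambda_cv,
    select_lambda_ebic,
)
from .cohort import Cohort
from .network import PairwiseNetwork

__all__ = [
    "MGMConfig",
    "NodewiseFit",
    "DiseaseNetworkModel",
    "DiseaseNetworkResults",
    "fit_nodewise",
    "node_accuracy",
    "l1_logistic",
    "lambda_path",
    "select_lambda_cv",
    "select_lambda_ebic",
]

K_ORDER = 2  # pairwise interactions only


@dataclass(frozen=True)
class MGMConfig:
    rule: str = "AND"                   # AND | OR
    lambda_selection: str = "cv"        # cv | ebic
    cv_rule: str = "1se"                # min | 1se (support-recovery default)
    cv_folds: int = 10
    lambda_grid_size: int = 30
    ebic_gamma: float = 0.25
    seed: int = 0
    debias: bool = False                # unpenalized refit on the selected support
    min_edge_weight: float = 1e-6       # numerical noise floor

    def __post_init__(self) -> None:
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.lambda_selection not in ("cv", "ebic"):
            raise ValueError("lambda_selection must be 'cv' or 'ebic'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")


@dataclass
class NodewiseFit:
    """Per-disease penalized regression of one node on all others."""

    code: str
    others: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    lambda_: float
    degenerate: bool = False
    fold_ids: np.ndarray | None = None
    accuracy: float | None = None

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(o for o, b in zip(self.others, self.coef) if b != 0.0)

    def coefficient_for(self, other: str) -> float:
        return float(self.coef[self.others.index(other)])


class DiseaseNetworkModel:
    """Nodewise Ising-network estimator bound to a cohort.

    ``fit()`` runs one penalized logistic regression per disease and
    aggregates the directed coefficients into an undirected
    :class:`~morbnet.network.PairwiseNetwork`.
    """

    def __init__(self, cohort: Cohort, config: MGMConfig | None = None):
        self.cohort = cohort
        self.config = config or MGMConfig()
        if len(cohort.catalog) < 2:
            raise ValueError("need at least two diseases")
        if cohort.n < 50:
            warnings.warn(f"small sample (n={cohort.n}): network estimates will be unstable")

    def fit(self) -> "DiseaseNetworkResults":
        import zlib

        cfg = self.config
        codes = self.cohort.catalog.codes
        X = self.cohort.X.astype(np.float64)
        n, p = X.shape
        # per-node seeds keyed to the disease label, not the column slot, so
        # permuting catalog columns permutes the fitted network identically
        node_seeds = {
            code: int(
                np.random.SeedSequence(
                    [cfg.seed, zlib.crc32(code.encode())]
                ).generate_state(1)[0] % (2**31)
            )
            for code in codes
        }
        fits: dict[str, NodewiseFit] = {}
        for s, code in enumerate(codes):
            y = X[:, s]
            others = tuple(c for c in codes if c != code)
            Xo = np.ascontiguousarray(np.delete(X, s, axis=1))
            if y.min() == y.max():
                warnings.warn(f"disease {code} is constant: node kept but isolated")
                pbar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
                fits[code] = NodewiseFit(
                    code=code, others=others,
                    intercept=float(np.log(pbar / (1 - pbar))),
                    coef=np.zeros(p - 1), lambda_=np.inf, degenerate=True,
                )
                continue
            grid = lambda_path(y, Xo, grid_size=cfg.lambda_grid_size)
            if cfg.lambda_selection == "cv":
                lam, _, fold_ids = select_lambda_cv(
                    y, Xo, cfg.cv_folds, grid, seed=node_seeds[code],
                    rule=cfg.cv_rule,
                )
                B, B0 = _solver.fit_path(y, Xo, grid)
            else:
                lam, _, (B, B0) = select_lambda_ebic(y, Xo, grid, gamma=cfg.ebic_gamma)
                fold_ids = None
            li = int(np.argmin(np.abs(grid - lam)))
            coef = B[li].copy()
            b0 = float(B0[li])
            if cfg.debias and np.any(coef != 0.0):
                b0, coef = _debias_refit(y, Xo, coef, b0)
            fits[code] = NodewiseFit(
                code=code, others=others, intercept=b0, coef=coef,
                lambda_=float(lam), fold_ids=fold_ids,
            )
        network = aggregate_network(fits, codes, rule=cfg.rule,
                                    min_edge_weight=cfg.min_edge_weight)
        return DiseaseNetworkResults(self, fits, network)


def _debias_refit(y, Xo, coef, b0):
    """Unpenalized ML refit restricted to the selected support, removing the
    shrinkage bias of the lasso while keeping its selection."""
    from .bridging import irls_logistic

    supp = np.nonzero(coef)[0]
    try:
        params, _, converged = irls_logistic(y, Xo[:, supp])
    except np.linalg.LinAlgError:
        return b0, coef
    if not converged or np.any(np.abs(params) > 20):
        return b0, coef  # keep the penalized fit in (near-)separated nodes
    new = np.zeros_like(coef)
    new[supp] = params[1:]
    return float(params[0]), new


def aggregate_network(fits: dict, codes, rule: str = "AND",
                      min_edge_weight: float = 1e-6) -> PairwiseNetwork:
    """Combine directed nodewise coefficients into one undirected network.

    AND rule: the edge (s,t) exists iff both beta_{s<-t} and beta_{t<-s}
    are nonzero; its weight is their mean. OR rule: either suffices, the
    absent coefficient entering the mean as 0. Sign conflicts are kept as
    edges with weight = mean absolute magnitude and flagged
    ``sign_consistent=False``.
    """
    net = PairwiseNetwork(nodes=tuple(codes), edges={})
    for i, s in enumerate(codes):
        for t in codes[i + 1:]:
            b_st = fits[s].coefficient_for(t)
            b_ts = fits[t].coefficient_for(s)
            if rule == "AND":
                present = b_st != 0.0 and b_ts != 0.0
            else:
                present = b_st != 0.0 or b_ts != 0.0
            if not present:
                continue
            if b_st * b_ts < 0:
                weight = (abs(b_st) + abs(b_ts)) / 2.0
                consistent = False
            else:
                weight = (b_st + b_ts) / 2.0
                consistent = True
            if abs(weight) >= min_edge_weight:
                net.add_edge(s, t, weight, sign_consistent=consistent)
    return net


class DiseaseNetworkResults:
    """Fitted nodewise network: per-node fits, the aggregated network, and
    accuracy/diagnostic reporting."""

    def __init__(self, model: DiseaseNetworkModel, fits: dict, network: PairwiseNetwork):
        self.model = model
        self.config = model.config
        self.fits = fits
        self.network = network

    @property
    def codes(self) -> tuple[str, ...]:
        return self.model.cohort.catalog.codes

    def accuracy(self, scheme: str = "within_sample") -> pd.Series:
        acc = node_accuracy(self.fits, self.model.cohort, scheme=scheme)
        for code, a in acc.items():
            self.fits[code].accuracy = float(a)
        return acc

    def communities(self):
        from .netmetrics import detect_communities

        return detect_communities(self.network)

    def centralities(self, **kwargs) -> pd.DataFrame:
        from .netmetrics import compute_centralities

        return compute_centralities(self.network, **kwargs)

    def summary(self, scheme: str = "within_sample") -> pd.DataFrame:
        acc = self.accuracy(scheme=scheme)
        rows = []
        for code in self.codes:
            f = self.fits[code]
            rows.append(
                {
                    "disease": code,
                    "lambda": f.lambda_,
                    "support_size": len(f.support),
                    "degree": self.network.degree(code),
                    "accuracy": acc[code],
                    "degenerate": f.degenerate,
                }
            )
        return pd.DataFrame(rows)


def fit_nodewise(cohort: Cohort, config: MGMConfig | None = None):
    """Functional entry point: returns ``(fits, network)``."""
    res = DiseaseNetworkModel(cohort, config).fit()
    return res.fits, res.network


def node_accuracy(fits: dict, cohort: Cohort, scheme: str = "within_sample") -> pd.Series:
    """Per-disease classification accuracy of the nodewise fits.

    ``within_sample``: fraction of persons with 1{p-hat > 0.5} equal to the
    observed indicator, under the stored fit. ``cv``: the same proportion on
    held-out folds, reusing each node's fold split and refitting per fold at
    the selected penalty (falls back to within-sample for nodes without a
    stored split, e.g. EBIC-selected or degenerate nodes).
    """
    if scheme not in ("within_sample", "cv"):
        raise ValueError("scheme must be 'within_sample' or 'cv'")
    X = cohort.X.astype(np.float64)
    codes = cohort.catalog.codes
    idx = {c: i for i, c in enumerate(codes)}
    out = {}
    for code, f in fits.items():
        y = X[:, idx[code]]
        Xo = np.delete(X, idx[code], axis=1)
        if scheme == "within_sample" or f.fold_ids is None or f.degenerate:
            mu = predict_proba(f.intercept, f.coef, Xo)
            out[code] = float(np.mean((mu > 0.5) == (y == 1)))
            continue
        correct = 0
        for k in np.unique(f.fold_ids):
            te = f.fold_ids == k
            tr = ~te
            if y[tr].min() == y[tr].max():
                mu = np.full(te.sum(), y[tr].mean())
            else:
                b0, coef = l1_logistic(y[tr], Xo[tr], f.lambda_)
                mu = predict_proba(b0, coef, Xo[te])
            correct += int(np.sum((mu > 0.5) == (y[te] == 1)))
        out[code] = correct / len(y)
    return pd.Series(out, name="accuracy")
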