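"""Synthetic cohort generation from planted-structure pairwise Markov random fields.

The survey data behind published multimorbidity networks are rarely
deposited, so every downstream stage of this package is exercised on
synthetic cohorts whose generative structure is known exactly. Binary
disease vectors x in {0,1}^p are drawn from an Ising-type model

    P(x) ~ exp( h.x + 1/2 x' W x ),   W symmetric, zero diagonal,

by Gibbs sampling from the full conditionals
P(x_s = 1 | rest) = logistic(h_s + sum_t W_st x_t). The {0,1} coding is
deliberate: the coefficients of a nodewise logistic regression of each
disease on all others then equal the couplings W directly, which makes
parameter recovery a clean end-to-end check.

Planted designs mirror the qualitative structure reported for disease
networks in older adults: block communities of strongly co-occurring
conditions, a small number of bridge diseases attaching several blocks,
and a few fully isolated conditions, with marginal prevalences in the
2-45% range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .catalog import DiseaseCatalog
from .cohort import (
    AGE_LEVELS,
    Cohort,
    EDUCATION_LEVELS,
    GENDER_LEVELS,
    INCOME_LEVELS,
)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class IsingParameters:
    """Couplings ``W`` (symmetric, zero diagonal) and thresholds ``h``."""

    W: np.ndarray
    h: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        p = len(self.nodes)
        if self.W.shape != (p, p):
            raise ValueError("W shape must match node count")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0, atol=1e-12):
            raise ValueError("W must have zero diagonal")
        if self.h.shape != (p,):
            raise ValueError("h shape must match node count")


@dataclass
class Bridge:
    node: str
    attach_blocks: tuple[int, ...]
    w_bridge: float
    attach_per_block: int = 2
    # per attached block, index of the first member to attach to; lets two
    # bridges share a block without sharing attachment nodes
    attach_offsets: tuple[int, ...] | None = None


@dataclass
class PlantedDesign:
    """Blocks + bridges + isolates partitioning the catalog, with target marginals."""

    nodes: tuple[str, ...]
    blocks: tuple[tuple[str, ...], ...]
    w_in: float
    bridges: tuple[Bridge, ...] = ()
    isolates: tuple[str, ...] = ()
    h_spec: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.blocks = tuple(tuple(b) for b in self.blocks)
        self.isolates = tuple(self.isolates)
        if self.w_in <= 0:
            raise ValueError("w_in must be positive")
        claimed: list[str] = []
        for b in self.blocks:
            claimed.extend(b)
        claimed.extend(br.node for br in self.bridges)
        claimed.extend(self.isolates)
        if len(set(claimed)) != len(claimed):
            raise ValueError("blocks, bridges and isolates must be disjoint")
        if set(claimed) != set(self.nodes):
            raise ValueError("blocks + bridges + isolates must partition the node set")
        h = dict(self.h_spec)
        for c in self.nodes:
            h.setdefault(c, 0.2)
            if not (0.0 < h[c] < 1.0):
                raise ValueError(f"target marginal for {c} must be in (0,1)")
        self.h_spec = h

    @property
    def bridge_nodes(self) -> tuple[str, ...]:
        return tuple(br.node for br in self.bridges)

    def coupling_matrix(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.nodes)}
        p = len(self.nodes)
        W = np.zeros((p, p))
        for block in self.blocks:
            for a in block:
                for b in block:
                    if a != b:
                        W[idx[a], idx[b]] = self.w_in
        for br in self.bridges:
            i = idx[br.node]
            offsets = br.attach_offsets or (0,) * len(br.attach_blocks)
            for bi, off in zip(br.attach_blocks, offsets):
                members = sorted(self.blocks[bi], key=lambda c: self.nodes.index(c))
                for m in members[off: off + br.attach_per_block]:
                    j = idx[m]
                    W[i, j] = W[j, i] = br.w_bridge
        return W

    def true_edge_set(self) -> set:
        W = self.coupling_matrix()
        edges = set()
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if W[i, j] != 0.0:
                    u, v = self.nodes[i], self.nodes[j]
                    edges.add((u, v) if u <= v else (v, u))
        return edges

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "blocks": [list(b) for b in self.blocks],
            "w_in": self.w_in,
            "bridges": [
                {
                    "node": br.node,
                    "attach_blocks": list(br.attach_blocks),
                    "w_bridge": br.w_bridge,
                    "attach_per_block": br.attach_per_block,
                    "attach_offsets": list(br.attach_offsets) if br.attach_offsets else None,
                }
                for br in self.bridges
            ],
            "isolates": list(self.isolates),
            "h_spec": dict(self.h_spec),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlantedDesign":
        return cls(
            nodes=tuple(d["nodes"]),
            blocks=tuple(tuple(b) for b in d["blocks"]),
            w_in=float(d["w_in"]),
            bridges=tuple(
                Bridge(
                    node=br["node"],
                    attach_blocks=tuple(br["attach_blocks"]),
                    w_bridge=float(br["w_bridge"]),
                    attach_per_block=int(br.get("attach_per_block", 2)),
                    attach_offsets=tuple(br["attach_offsets"])
                    if br.get("attach_offsets") else None,
                )
                for br in d.get("bridges", ())
            ),
            isolates=tuple(d.get("isolates", ())),
            h_spec=dict(d.get("h_spec", {})),
        )


def default_design(catalog: DiseaseCatalog | None = None) -> PlantedDesign:
    """Reference 32-node design: five block communities (sizes 6,6,5,5,4),
    two bridge diseases (hypertension D1, depression D20) each attaching
    three blocks, and four isolated conditions. Target marginals span the
    0.03-0.42 range typical of chronic-disease prevalences in adults 50+."""
    catalog = catalog or DiseaseCatalog.default()
    nodes = catalog.codes
    blocks = (
        ("D2", "D3", "D4", "D12", "D15", "D23"),    # cardiovascular/metabolic
        ("D5", "D6", "D7", "D8", "D27", "D31"),     # musculoskeletal
        ("D9", "D10", "D11", "D17", "D28"),         # respiratory/allergic
        ("D13", "D18", "D19", "D25", "D32"),        # digestive
        ("D14", "D21", "D22", "D24"),               # mental/neurological
    )
    bridges = (
        Bridge(node="D1", attach_blocks=(0, 1, 3), w_bridge=0.8),
        Bridge(node="D20", attach_blocks=(1, 2, 4), w_bridge=0.8,
               attach_offsets=(2, 0, 0)),
    )
    isolates = ("D16", "D26", "D29", "D30")
    h_spec = {
        "D1": 0.42, "D20": 0.15,
        "D2": 0.07, "D3": 0.06, "D4": 0.10, "D12": 0.20, "D15": 0.33, "D23": 0.04,
        "D5": 0.22, "D6": 0.25, "D7": 0.26, "D8": 0.30, "D27": 0.12, "D31": 0.07,
        "D9": 0.15, "D10": 0.07, "D11": 0.08, "D17": 0.09, "D28": 0.12,
        "D13": 0.06, "D18": 0.10, "D19": 0.03, "D25": 0.12, "D32": 0.18,
        "D14": 0.10, "D21": 0.14, "D22": 0.05, "D24": 0.13,
        "D16": 0.17, "D26": 0.08, "D29": 0.05, "D30": 0.18,
    }
    return PlantedDesign(
        nodes=nodes, blocks=blocks, w_in=1.0, bridges=bridges,
        isolates=isolates, h_spec=h_spec,
    )


# ---------------------------------------------------------------------------
# threshold calibration and sampling


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def mean_field_thresholds(W: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve the mean-field consistency equation m = logistic(h + W m) for h.

    With the target marginals fixed, the per-node equation is monotone in
    h_s and its root is available in closed form: h = logit(m) - W m.
    """
    return _logit(targets) - W @ targets


def build_planted_ising(
    design: PlantedDesign,
    calibrate: str = "gibbs",
    seed: int = 0,
    rounds: int = 12,
    burn_in: int = 100,
) -> IsingParameters:
    """Materialize couplings and thresholds for a planted design.

    Thresholds start at the mean-field solution for the target marginals
    and, with ``calibrate='gibbs'`` (default), are refined by a seeded
    damped stochastic-approximation loop until the *realized* Gibbs
    marginals match the targets: mean-field calibration alone is biased
    inside strongly coupled blocks, and undamped updates oscillate because
    shifting every threshold in a block feeds back through the couplings.
    Early rounds use a fixed damping on small calibration samples, later
    rounds a decreasing Robbins-Monro step on larger ones.
    ``calibrate='mean_field'`` skips the refinement. Deterministic given
    ``seed``, so a parameter set can be built once and reused across
    sampling seeds.
    """
    W = design.coupling_matrix()
    targets = np.array([design.h_spec[c] for c in design.nodes])
    h = mean_field_thresholds(W, targets)
    if calibrate == "mean_field":
        return IsingParameters(W=W, h=h, nodes=design.nodes)
    if calibrate != "gibbs":
        raise ValueError(f"unknown calibration mode: {calibrate!r}")
    rng_seeds = np.random.SeedSequence(seed).generate_state(rounds) % (2**31)
    params = IsingParameters(W=W, h=h, nodes=design.nodes)
    for r in range(rounds):
        if r < 4:
            step, n_cal = 0.6, 2000
        else:
            step, n_cal = max(0.3, 2.0 / (r + 2)), 6000
        X = sample_ising(params, n=n_cal, burn_in=burn_in, seed=int(rng_seeds[r]))
        realized = X.mean(axis=0)
        params.h = params.h + step * (_logit(targets) - _logit(realized))
    return params


def sample_ising(
    params: IsingParameters,
    n: int,
    burn_in: int = 200,
    thin: int = 1,
    seed: int = 0,
    mode: str = "independent",
) -> np.ndarray:
    """Draw ``n`` binary disease vectors by Gibbs sampling.

    ``mode='independent'`` (default) runs one independent chain per row —
    ``burn_in`` full sweeps from a Bernoulli(logistic(h)) start — which
    guarantees exchangeable rows, matching the independent-respondents
    assumption of a survey. ``mode='chain'`` runs a single chain and keeps
    every ``thin``-th state after burn-in. Fixed seed gives bit-identical
    output.

    The sweep visits nodes in sorted-label order and draws its uniforms in
    that order, so relabeling/permuting the design's nodes permutes the
    sampled columns identically (exact label equivariance).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if burn_in < 0 or thin < 1:
        raise ValueError("burn_in must be >= 0 and thin >= 1")
    W, h = params.W, params.h
    p = len(params.nodes)
    order = sorted(range(p), key=lambda s: params.nodes[s])
    rng = np.random.default_rng(seed)
    base = 1.0 / (1.0 + np.exp(-h))
    if mode == "independent":
        Xf = np.empty((n, p), dtype=np.float64)
        for s in order:
            Xf[:, s] = rng.random(n) < base[s]
        for _ in range(burn_in):
            for s in order:
                eta = h[s] + Xf @ W[:, s]
                prob = 1.0 / (1.0 + np.exp(-eta))
                Xf[:, s] = rng.random(n) < prob
        return Xf.astype(np.int8)
    if mode == "chain":
        x = np.empty(p, dtype=np.float64)
        for s in order:
            x[s] = rng.random() < base[s]
        out = np.empty((n, p), dtype=np.int8)
        kept = 0
        sweep = 0
        while kept < n:
            for s in order:
                eta = h[s] + x @ W[:, s]
                prob = 1.0 / (1.0 + np.exp(-eta))
                x[s] = rng.random() < prob
            sweep += 1
            if sweep > burn_in and (sweep - burn_in) % thin == 0:
                out[kept] = x.astype(np.int8)
                kept += 1
        return out
    raise ValueError(f"unknown sampling mode: {mode!r}")


# ---------------------------------------------------------------------------
# demographics and regression harness


@dataclass
class OutcomeLink:
    """Direct logistic link for generating a binary outcome from covariates.

    ``betas`` maps predictor names to log-odds coefficients. Disease codes
    refer to the binary disease columns; demographic levels are addressed
    as ``"age_group:65-74"``-style dummy names.
    """

    intercept: float = 0.0
    betas: Mapping[str, float] = field(default_factory=dict)


@dataclass
class DemographicSpec:
    gender_probs: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.5, "F": 0.5}
    )
    age_probs: Mapping[str, float] = field(
        default_factory=lambda: {"50-64": 0.45, "65-74": 0.30, "75plus": 0.25}
    )
    income_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Q1": 0.25, "Q2": 0.25, "Q3": 0.25, "Q4": 0.25}
    )
    education_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Primary": 0.50, "Secondary": 0.30, "Tertiary": 0.20}
    )
    outcome_link: OutcomeLink | None = None

    def __post_init__(self) -> None:
        for name, probs, levels in (
            ("gender_probs", self.gender_probs, GENDER_LEVELS),
            ("age_probs", self.age_probs, AGE_LEVELS),
            ("income_probs", self.income_probs, INCOME_LEVELS),
            ("education_probs", self.education_probs, EDUCATION_LEVELS),
        ):
            vec = np.array([probs.get(l, 0.0) for l in levels], dtype=float)
            if not np.isclose(vec.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1")


def _draw_categorical(rng, levels, probs, n):
    p = np.array([probs.get(l, 0.0) for l in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def attach_demographics(
    X: np.ndarray,
    spec: DemographicSpec,
    seed: int,
    catalog: DiseaseCatalog | None = None,
    gender: str | None = None,
    id_prefix: str = "P",
) -> Cohort:
    """Wrap a binary disease matrix into a full cohort with demographics
    drawn independently of the diseases. ``gender`` forces a single level
    (used when male and female cohorts are simulated from separate designs).
    """
    catalog = catalog or DiseaseCatalog.default()
    X = np.asarray(X)
    n, p = X.shape
    if p != len(catalog):
        raise ValueError("disease matrix width must match catalog")
    rng = np.random.default_rng(seed)
    import pandas as pd

    df = pd.DataFrame(X, columns=list(catalog.codes))
    df.insert(0, "id", [f"{id_prefix}{i:06d}" for i in range(n)])
    if gender is not None:
        df.insert(1, "gender", gender)
    else:
        df.insert(1, "gender", _draw_categorical(rng, GENDER_LEVELS, spec.gender_probs, n))
    df.insert(2, "age_group", _draw_categorical(rng, AGE_LEVELS, spec.age_probs, n))
    df.insert(3, "income_q", _draw_categorical(rng, INCOME_LEVELS, spec.income_probs, n))
    df.insert(4, "education", _draw_categorical(rng, EDUCATION_LEVELS, spec.education_probs, n))
    return Cohort(df, catalog)


def simulate_cohort(
    design: PlantedDesign,
    n: int,
    seed: int,
    spec: DemographicSpec | None = None,
    params: IsingParameters | None = None,
    burn_in: int = 200,
    gender: str | None = None,
    id_prefix: str = "P",
) -> Cohort:
    """Planted-Ising disease matrix + demographics in one call.

    ``params`` may be passed to reuse a calibrated parameter set across
    seeds (calibration is deterministic given the design, so this is a
    pure speed optimization).
    """
    spec = spec or DemographicSpec()
    if params is None:
        params = build_planted_ising(design)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    X = sample_ising(params, n=n, burn_in=burn_in, seed=int(seeds[0]))
    default = DiseaseCatalog.default()
    catalog = default if design.nodes == default.codes else DiseaseCatalog.from_codes(design.nodes)
    return attach_demographics(
        X, spec, seed=int(seeds[1]), catalog=catalog, gender=gender, id_prefix=id_prefix,
    )


def generate_regression_cohort(
    spec: DemographicSpec,
    n: int,
    seed: int,
    catalog: DiseaseCatalog | None = None,
    disease_prev: Mapping[str, float] | None = None,
) -> tuple[Cohort, np.ndarray]:
    """Cohort plus a binary outcome drawn from logistic(b0 + beta.x).

    Disease predictors are independent Bernoulli columns (prevalence 0.2
    unless overridden per code); demographic dummies enter through
    ``spec.outcome_link.betas`` names like ``"education:Tertiary"``. Used
    to validate odds-ratio recovery of the bridging regression.
    """
    if spec.outcome_link is None:
        raise ValueError("spec.outcome_link is required")
    catalog = catalog or DiseaseCatalog.default()
    rng = np.random.default_rng(seed)
    prev = {c: 0.2 for c in catalog.codes}
    if disease_prev:
        prev.update(disease_prev)
    X = np.column_stack(
        [(rng.random(n) < prev[c]).astype(np.int8) for c in catalog.codes]
    )
    demo_seed = int(rng.integers(0, 2**31))
    cohort = attach_demographics(X, spec, seed=demo_seed, catalog=catalog)
    link = spec.outcome_link
    lp = np.full(n, link.intercept, dtype=float)
    for name, beta in link.betas.items():
        if name in catalog.codes:
            col = cohort.df[name].to_numpy(dtype=float)
        elif ":" in name:
            field_name, level = name.split(":", 1)
            col = (cohort.df[field_name] == level).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown predictor in outcome_link: {name!r}")
        lp += beta * col
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(np.int8)
    return cohort, y
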