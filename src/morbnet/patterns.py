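"""Person-level pattern assignment and the complex (multisystem) phenotype.

A person is assigned to a multimorbidity pattern when they carry at least
``min_count`` diseases belonging to that community (default 2, echoing the
two-or-more-chronic-diseases multimorbidity criterion). Assignment is
non-exclusive, so pattern prevalences may jointly exceed 100%. The complex
phenotype marks persons assigned to two or more patterns simultaneously.

Published pattern prevalences never come with an explicit person-level
rule; the rule here is therefore declared and configurable rather than
presented as canonical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, DEMOGRAPHIC_LEVELS
from .netmetrics import CommunityPartition

Z_CRIT = float(norm.ppf(0.975))  # 1.959964 at the 95% confidence level


@dataclass
class PatternAssignment:
    """Per-person pattern sets plus the derived complex flag."""

    table: pd.DataFrame          # person_id, patterns (frozenset), complex_flag
    pattern_ids: tuple[int, ...]
    min_count: int
    cohort: Cohort = field(repr=False, default=None)

    @property
    def complex_flags(self) -> np.ndarray:
        return self.table["complex_flag"].to_numpy()

    def prevalence(self, stratify: str | None = None) -> pd.DataFrame:
        """Pattern (and complex-phenotype) prevalence, optionally by stratum."""
        rows = []
        if stratify is None:
            groups = [("all", np.ones(len(self.table), dtype=bool))]
        else:
            col = self.cohort.df[stratify]
            groups = [
                (level, (col == level).to_numpy())
                for level in DEMOGRAPHIC_LEVELS[stratify]
            ]
        pats = self.table["patterns"]
        for level, mask in groups:
            n = int(mask.sum())
            for pid in self.pattern_ids:
                has = np.array([pid in s for s in pats])
                rows.append({
                    "pattern": pid, "stratum": level,
                    "count": int(has[mask].sum()), "n": n,
                    "prevalence": float(has[mask].mean()) if n else float("nan"),
                })
            cx = self.complex_flags
            rows.append({
                "pattern": "complex", "stratum": level,
                "count": int(cx[mask].sum()), "n": n,
                "prevalence": float(cx[mask].mean()) if n else float("nan"),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df["patterns"] = df["patterns"].map(
            lambda s: ";".join(str(p) for p in sorted(s))
        )
        df.to_csv(path, index=False)


def assign_patterns(
    cohort: Cohort, partition: CommunityPartition, min_count: int = 2
) -> PatternAssignment:
    """Assign persons to patterns: pattern P is held iff the person carries
    at least ``min_count`` diseases whose community is P. The complex flag
    is true iff two or more patterns are held."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    comms = partition.communities()
    missing = [c for c in cohort.catalog.codes if c not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover diseases: {missing}")
    unreachable = [cid for cid, codes in comms.items() if len(codes) < min_count]
    if unreachable:
        warnings.warn(
            f"communities {unreachable} have fewer than min_count={min_count} "
            "diseases and can never be assigned"
        )
    X = cohort.X
    idx = {c: i for i, c in enumerate(cohort.catalog.codes)}
    pattern_ids = tuple(sorted(comms))
    counts = {
        cid: X[:, [idx[c] for c in codes]].sum(axis=1)
        for cid, codes in comms.items()
    }
    patterns = []
    for i in range(cohort.n):
        held = frozenset(cid for cid in pattern_ids if counts[cid][i] >= min_count)
        patterns.append(held)
    table = pd.DataFrame(
        {
            "person_id": cohort.person_ids.to_numpy(),
            "patterns": patterns,
            "complex_flag": [len(s) >= 2 for s in patterns],
        }
    )
    return PatternAssignment(
        table=table, pattern_ids=pattern_ids, min_count=min_count, cohort=cohort
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, bool, bool]:
    """Pooled-variance two-proportion z statistic.

    Returns ``(z, significant at alpha=0.05 two-sided, defined)``. When the
    pooled variance is zero (both proportions 0 or both 1) the statistic is
    undefined and reported as non-significant with ``defined=False``.
    """
    if n1 == 0 or n2 == 0:
        return float("nan"), False, False
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var <= 0:
        return float("nan"), False, False
    z = (p1 - p2) / np.sqrt(var)
    return float(z), bool(abs(z) >= Z_CRIT), True


def compare_prevalence(
    assignment: PatternAssignment, strata: str = "gender"
) -> pd.DataFrame:
    """Gender (or other two-level stratum) comparison of pattern prevalences
    with a pooled two-proportion z-test at the 95% confidence level."""
    levels = DEMOGRAPHIC_LEVELS[strata][:2]
    prev = assignment.prevalence(stratify=strata)
    a = prev[prev["stratum"] == levels[0]].set_index("pattern")
    b = prev[prev["stratum"] == levels[1]].set_index("pattern")
    if a["n"].iloc[0] == 0 or b["n"].iloc[0] == 0:
        raise ValueError(f"both {strata} strata must be nonempty")
    rows = []
    for pid in list(assignment.pattern_ids) + ["complex"]:
        z, sig, defined = two_proportion_z(
            int(a.loc[pid, "count"]), int(a.loc[pid, "n"]),
            int(b.loc[pid, "count"]), int(b.loc[pid, "n"]),
        )
        rows.append({
            "pattern": pid,
            f"prevalence_{levels[0]}": a.loc[pid, "prevalence"],
            f"prevalence_{levels[1]}": b.loc[pid, "prevalence"],
            "z": z,
            "significant": sig,
            "defined": defined,
        })
    return pd.DataFrame(rows)
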