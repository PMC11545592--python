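"""Group comparisons and rarefaction.

The two prey groups (fish vs benthic invertebrates) are compared per
sample: for each faecal sample, the group's *read share* (sum of the
sample's read proportions over the group's items) and the group's
*richness* (number of the group's items detected in the sample). The
two resulting per-sample vectors are compared with a two-sided
Mann-Whitney U test.

The U statistic uses midranks for ties. The exact two-sided p-value is
a full enumeration over all C(n1+n2, n1) assignments of the pooled
(mid)ranks to the first sample, rejecting on |U - n1*n2/2|; by default
it is used when min(n1, n2) <= 8 and there are no ties, otherwise the
tie-corrected normal approximation with a 0.5 continuity correction is
applied.

Rarefaction gives the expected richness at a reduced sampling effort
under uniform random subsampling without replacement, via the exact
hypergeometric form

    E[S_m] = sum_i [ 1 - C(N - N_i, m) / C(N, m) ]

for individual-based curves (N_i reads of item i, N total reads), and
the same form with per-item occupancy counts F_i out of S samples for
sample-based curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, rankdata

from .io import PreyTable, ValidationError
from .metrics import compute_foo


def summarise_groups(prey: PreyTable) -> pd.DataFrame:
    """Per-sample read share and richness for every prey group present."""
    counts = prey.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    groups = sorted(set(prey.groups.values()))
    rows = []
    for g in groups:
        idx = [prey.items.index(i) for i in prey.group_items(g)]
        sub = counts[:, idx]
        share = sub.sum(axis=1) / totals
        richness = (sub > 0).sum(axis=1)
        for k, sample in enumerate(prey.sample_ids):
            rows.append(
                {
                    "sample_id": sample,
                    "group": g,
                    "rel_abundance_share": float(share[k]),
                    "richness": int(richness[k]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MWUResult:
    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= self.n1 * self.n2:
            raise ValidationError(f"U = {self.U} outside [0, n1*n2]")
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValidationError(f"p = {self.p_two_sided} outside (0, 1]")


def _u_statistic(ranks1: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks1.sum() - n1 * (n1 + 1) / 2.0)


def _exact_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided p by enumerating every split of the pooled (mid)ranks."""
    n = pooled_ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = _u_statistic(pooled_ranks[list(idx)], n1, n2)
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def _normal_p(pooled_ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_limit: int = 8,
) -> MWUResult:
    """Two-sided Mann-Whitney U test; U is the statistic of ``x``.

    ``mode="auto"`` picks full enumeration for small tie-free samples
    (min(n1, n2) <= ``exact_limit``) and the normal approximation
    otherwise; ``"exact"`` forces enumeration (valid with ties, as a
    permutation test on midranks); ``"normal_approx"`` forces the
    approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1, n2)
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (mode == "auto" and min(n1, n2) <= exact_limit and not has_ties):
        return MWUResult(u_obs, n1, n2, _exact_p(ranks, n1, u_obs), "exact")
    return MWUResult(u_obs, n1, n2, _normal_p(ranks, n1, n2, u_obs), "normal_approx")


def compare_prey_groups(
    prey: PreyTable,
    group_a: str = "fish",
    group_b: str = "benthic_invertebrate",
    mode: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney comparison of read share and richness between groups.

    One row per statistic; the U reported is that of ``group_a``.
    """
    summary = summarise_groups(prey)
    a = summary[summary["group"] == group_a]
    b = summary[summary["group"] == group_b]
    if a.empty or b.empty:
        raise ValidationError("both prey groups must be present in the table")
    rows = []
    for stat in ("rel_abundance_share", "richness"):
        res = mann_whitney_u(a[stat].to_numpy(), b[stat].to_numpy(), mode=mode)
        rows.append(
            {
                "statistic": stat,
                "n1": res.n1,
                "n2": res.n2,
                "U": res.U,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rarefaction


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefy_individual(counts: Sequence[int], m: int) -> float:
    """Expected richness when drawing ``m`` of the N reads without replacement."""
    arr = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    if arr.size and arr.min() < 0:
        raise ValidationError("counts must be non-negative")
    n_total = int(arr.sum())
    if not 0 <= m <= n_total:
        raise ValidationError(f"m = {m} outside [0, N = {n_total}]")
    if m == 0:
        return 0.0
    remaining = n_total - arr
    term = np.zeros(arr.size)
    feasible = remaining >= m  # else the item is certain to appear
    term[feasible] = np.exp(_log_comb(remaining[feasible], m) - _log_comb(n_total, m))
    return float(np.sum(1.0 - term))


def rarefy_samples(prey: PreyTable, s: int) -> float:
    """Expected item richness over a random subset of ``s`` samples."""
    n_samples = prey.n_samples
    if not 1 <= s <= n_samples:
        raise ValidationError(f"s = {s} outside [1, S = {n_samples}]")
    occ = compute_foo(prey)["occurrence_count"].to_numpy()
    remaining = n_samples - occ
    term = np.zeros(occ.size)
    feasible = remaining >= s
    term[feasible] = np.exp(_log_comb(remaining[feasible], s) - _log_comb(n_samples, s))
    return float(np.sum(1.0 - term))


@dataclass
class RarefactionCurve:
    mode: str  # "sample_based" | "individual_based"
    points: list[tuple[int, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["effort", "expected_richness"])


def rarefaction_curve(
    prey: PreyTable,
    mode: str = "sample_based",
    efforts: Sequence[int] | None = None,
) -> RarefactionCurve:
    """Rarefaction curve ending at the observed richness.

    Sample-based efforts default to 1..S; individual-based efforts
    default to ~25 points spanning 1..N (pooled reads over samples).
    """
    if mode == "sample_based":
        if efforts is None:
            efforts = list(range(1, prey.n_samples + 1))
        points = [(int(s), rarefy_samples(prey, int(s))) for s in efforts]
    elif mode == "individual_based":
        counts = prey.counts.sum(axis=0).to_numpy()
        n_total = int(counts.sum())
        if efforts is None:
            efforts = sorted(
                set(np.linspace(1, n_total, num=min(25, n_total), dtype=np.int64).tolist())
            )
        points = [(int(m), rarefy_individual(counts, int(m))) for m in efforts]
    else:
        raise ValidationError(f"unknown rarefaction mode {mode!r}")
    return RarefactionCurve(mode=mode, points=points)
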