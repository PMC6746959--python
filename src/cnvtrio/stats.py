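"""Carrier-asymmetry permutation test for recurrent CNV regions.

The null hypothesis is that the k = k_case + k_control carriers of a region
are assigned uniformly without replacement over all n_case + n_control
individuals.  Under this null the number of carriers landing in cases is
hypergeometric, which gives a closed-form one-sided p-value
(:func:`hypergeom_upper_tail`); the Monte Carlo estimate draws the same
statistic n_perm times and applies the add-one estimator so p is never
exactly zero.  The test is one-sided for case excess — the screen is for
case-only variants.

Default cohort denominators combine the discovery and WES-replication trio
sets: 2,458 probands vs 4,455 family controls.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: probands in the discovery (759) plus WES replication (1,699) trio cohorts
DEFAULT_N_CASE = 2458
#: family controls in the same two cohorts (1,346 + 3,109)
DEFAULT_N_CONTROL = 4455


@dataclass(frozen=True)
class PermutationResult:
    k_case: int
    k_control: int
    n_case: int
    n_control: int
    n_perm: int
    seed: int
    p_mc: float
    p_exact: float
    se_mc: float

    def __post_init__(self) -> None:
        if self.k_case > self.n_case or self.k_control > self.n_control:
            raise ValueError("carrier counts exceed cohort sizes")
        if self.p_mc < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p_mc below the add-one floor 1/(n_perm+1)")


def hypergeom_upper_tail(k_case: int, k: int, n_case: int, n_total: int) -> float:
    """P(X >= k_case) for X ~ Hypergeometric(n_total, n_case, k).

    The exact one-sided null of the carrier permutation test: k carriers
    placed uniformly among n_total individuals of whom n_case are cases.
    Computed in log space by scipy's survival function.
    """
    if not (0 <= k_case <= k <= n_total) or not (0 <= n_case <= n_total):
        raise ValueError(
            f"impossible configuration: k_case={k_case}, k={k}, "
            f"n_case={n_case}, n_total={n_total}"
        )
    if k_case > n_case:
        raise ValueError(f"k_case={k_case} exceeds n_case={n_case}")
    if k_case == 0:
        return 1.0
    return float(hypergeom.sf(k_case - 1, n_total, n_case, k))


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-region RNG seed < 2^31, independent of processing order."""
    return (master_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def carrier_permutation_test(
    k_case: int,
    k_control: int,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided Monte Carlo permutation test for case excess among carriers.

    Each permutation reassigns the k carrier labels uniformly without
    replacement over the n_case + n_control individuals; the case-carrier
    count of one such reassignment is a hypergeometric draw, which is how
    the permutations are sampled.  p_mc uses the add-one estimator
    (1 + #{permutations >= observed}) / (n_perm + 1); p_exact is the
    closed-form hypergeometric tail; se_mc = sqrt(p_mc (1-p_mc) / n_perm).
    """
    if min(k_case, k_control, n_case, n_control) < 0:
        raise ValueError("counts must be nonnegative")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if k_case > n_case or k_control > n_control:
        raise ValueError(
            f"carrier counts ({k_case}, {k_control}) exceed cohort sizes "
            f"({n_case}, {n_control})"
        )
    k = k_case + k_control
    n_total = n_case + n_control
    if k == 0:
        warnings.warn("region has zero carriers; p = 1.0 by convention")
        return PermutationResult(
            k_case, k_control, n_case, n_control, n_perm, seed, 1.0, 1.0, 0.0
        )
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_case, n_control, k, size=n_perm)
    hits = int(np.count_nonzero(draws >= k_case))
    p_mc = (1 + hits) / (n_perm + 1)
    p_exact = hypergeom_upper_tail(k_case, k, n_case, n_total)
    se_mc = float(np.sqrt(p_mc * (1 - p_mc) / n_perm))
    return PermutationResult(
        k_case, k_control, n_case, n_control, n_perm, seed, p_mc, p_exact, se_mc
    )


def test_regions(
    regions,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    n_perm: int = 10_000,
    master_seed: int = 0,
):
    """Run the carrier test on every region, seeding per region_id.

    Fills p_carrier (Monte Carlo), p_exact, n_perm and seed on each region;
    the per-region seed mixes the master seed with the region_id so results
    do not depend on region processing order.
    """
    for r in regions:
        seed = derive_seed(master_seed, r.region_id)
        res = carrier_permutation_test(
            r.n_case_carriers, r.n_control_carriers, n_case, n_control, n_perm, seed
        )
        r.p_carrier = res.p_mc
        r.p_exact = res.p_exact
        r.n_perm = n_perm
        r.seed = seed
    return regions


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (reported, never used to filter)."""
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])
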