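"""The site-substitution null model for convergent shared SNVs.

At one homologous site, each of ``k`` independent populations is assigned an
(original base, variant base) combination: 4 x 4 = 16 possibilities per
population, hence 16^k combinations in all. Of these, exactly 12 correspond
to every population undergoing the *same real* substitution (16 ordered base
pairs minus the 4 identities). Under random mutation alone, a fraction

    p(k) = 12 / 16^k

of same-site shared SNVs is therefore expected to carry the same
substitution: 12/256 for a pair of populations, 12/4,096 for a triplet. The
expected convergent count for a group sharing ``n`` same-site SNVs is
``p(k) * n``; an observed same-substitution count strictly exceeding that
expectation is evidence for gene flow / recombination or shared ancestry
rather than convergence.

Probabilities are exact rationals; floats appear only at the reporting edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd


def convergence_probability(k: int) -> Fraction:
    """Exact probability 12 / 16**k that k independent substitutions coincide."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return Fraction(12, 16**k)


def enumerate_matches(k: int) -> tuple[int, int]:
    """Brute-force census of the 16^k (original, variant) assignments.

    Counts assignments in which every population mutates (original != variant)
    and all k populations carry the identical (original, variant) pair.
    Exhaustive check of the closed form; guarded to k <= 5.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be in [1, 5]")
    combos = list(itertools.product(range(4), range(4)))  # (original, variant)
    n_matching = 0
    for assignment in itertools.product(combos, repeat=k):
        first = assignment[0]
        if first[0] != first[1] and all(a == first for a in assignment):
            n_matching += 1
    return n_matching, 16**k


def expected_convergent_exact(n_same_site: int, k: int) -> Fraction:
    if n_same_site < 0:
        raise ValueError("n_same_site must be >= 0")
    return convergence_probability(k) * n_same_site


def expected_convergent(n_same_site: int, k: int) -> float:
    """Expected number of same-substitution SNVs arising convergently among
    ``n_same_site`` shared sites in a group of ``k`` populations."""
    return float(expected_convergent_exact(n_same_site, k))


def classify_evidence(observed_same_substitution: float, expected: float) -> str:
    """Gene-flow/ancestry evidence iff observed strictly exceeds the
    (unrounded) convergent expectation."""
    if observed_same_substitution < 0 or expected < 0:
        raise ValueError("counts must be >= 0")
    return "gene_flow_or_ancestry" if observed_same_substitution > expected else "none"


@dataclass
class MonteCarloResult:
    fraction: float
    n_sites: int
    reps: int
    per_rep: np.ndarray
    ci99: tuple[float, float]
    analytic: float


def monte_carlo_convergence(
    n_sites: int, k: int, reps: int = 1, seed: int | None = None
) -> MonteCarloResult:
    """Empirical convergence fraction under the uniform model.

    Each population independently draws an original and a variant base
    uniformly (the model's 16 combinations, identities included); a site
    converges when all k populations hold the identical pair and it is a
    real change. The 99% CI is the normal approximation around the pooled
    empirical fraction.
    """
    if n_sites <= 0 or reps <= 0:
        raise ValueError("n_sites and reps must be positive")
    rng = np.random.default_rng(seed)
    fractions = np.empty(reps)
    for r in range(reps):
        orig = rng.integers(0, 4, size=(k, n_sites), dtype=np.uint8)
        var = rng.integers(0, 4, size=(k, n_sites), dtype=np.uint8)
        match = (
            (orig == orig[0]).all(axis=0)
            & (var == var[0]).all(axis=0)
            & (orig[0] != var[0])
        )
        fractions[r] = match.mean()
    p_hat = float(fractions.mean())
    n_total = n_sites * reps
    half = 2.5758293035489004 * np.sqrt(max(p_hat * (1 - p_hat), 1e-300) / n_total)
    return MonteCarloResult(
        fraction=p_hat,
        n_sites=n_sites,
        reps=reps,
        per_rep=fractions,
        ci99=(p_hat - half, p_hat + half),
        analytic=float(convergence_probability(k)),
    )


def format_expected(value: float, decimals: int = 2) -> str:
    """Rendering convention: exact zero prints "0", positive sub-unit
    expectations print "<1", others print with the given precision."""
    if value == 0:
        return "0"
    if value < 1:
        return "<1"
    return f"{value:.{decimals}f}"


def convergence_table(group_summary: pd.DataFrame) -> pd.DataFrame:
    """Augment a shared-SNV group summary with the null expectation and the
    evidence call (pairs use k=2, triplets k=3)."""
    rows = []
    for row in group_summary.itertuples(index=False):
        k = 2 if row.kind == "pair" else 3
        expected = expected_convergent(int(row.n_same_site), k)
        rows.append(
            {
                "group": row.group,
                "kind": row.kind,
                "n_same_site": int(row.n_same_site),
                "n_same_substitution": int(row.n_same_substitution),
                "expected_convergent": expected,
                "expected_display": format_expected(expected, 2 if k == 2 else 4),
                "evidence": classify_evidence(int(row.n_same_substitution), expected),
            }
        )
    return pd.DataFrame(rows)
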