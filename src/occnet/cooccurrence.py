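"""All-pairs co-occurrence testing with null-model calibration.

Every fragment pair is tested for association with the two-sided Fisher exact
test on its 2x2 joint-presence table, followed by Benjamini-Hochberg FDR
correction across all pairs. Two randomization nulls calibrate the result:

* a fixed-margin null (row AND column sums conserved; curveball trades or
  checkerboard swaps) re-runs the full test pipeline on randomized matrices
  to estimate the empirical false discovery rate of the significant set;
* an occupancy-preserving null (each fragment's row permuted independently
  across samples) yields the expected number of co-occurrences per pair and
  classifies significant pairs as positive (co-occurring more than expected)
  or negative (mutual exclusion).

The all-pairs Fisher p-values are computed by vectorized hypergeometric
enumeration grouped by margin pair, which makes the 100-replicate empirical
FDR loop affordable at the study's scale (hundreds of fragments, ~2e5 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import (
    ARCHAEAL,
    BACTERIAL,
    ContingencyTable2x2,
    FragmentAnnotation,
    PresenceAbsenceMatrix,
    ValidationError,
)

POSITIVE = "positive"
NEGATIVE = "negative"
UNCLASSIFIED = "unclassified"

# relative gate when comparing table probabilities, as in standard software
_REL_EPS = 1 + 1e-7


@dataclass(frozen=True)
class PairTestResult:
    """Fisher-test outcome for one unordered fragment pair."""

    fragment_1: str
    fragment_2: str
    table: ContingencyTable2x2
    p_raw: float
    p_adj: float
    significant: bool
    sign: str = UNCLASSIFIED
    expected_cooccurrence: float | None = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.fragment_1, self.fragment_2))

    @property
    def observed_cooccurrence(self) -> int:
        return self.table.a


@dataclass(frozen=True)
class FdrEstimate:
    mean_null_significant: float
    estimated_fdr: float
    observed_significant: int
    null_counts: tuple[int, ...]


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Counts panel for one data set: pair totals and domain breakdowns."""

    n_fragments: int
    n_bacterial: int
    n_archaeal: int
    n_potential_pairs: int
    n_correlated: int
    n_positive: int
    n_negative: int
    n_bacterial_pairs: int
    n_bacterial_pos: int
    n_bacterial_neg: int
    n_archaeal_pairs: int
    n_archaeal_pos: int
    n_archaeal_neg: int
    n_mixed_pairs: int
    n_mixed_pos: int
    n_mixed_neg: int
    randomized_mean_correlated: float | None = None
    estimated_fdr: float | None = None


def potential_pairs(n_fragments: int) -> int:
    """Number of unordered fragment pairs, n(n-1)/2."""
    return n_fragments * (n_fragments - 1) // 2


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums the hypergeometric probabilities of every table with the same margins
    whose probability does not exceed that of the observed table.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    n1 = a + b  # occupancy of first fragment
    n2 = a + c  # occupancy of second fragment
    lo = max(0, n1 + n2 - n)
    hi = min(n1, n2)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, n1, n2)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _REL_EPS].sum())
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pair indices (i, j) and co-occurrence counts a."""
    v = values.astype(np.int64)
    co = v @ v.T
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return iu, ju, co[iu, ju]


def _two_sided_pvalues(a: np.ndarray, n1: np.ndarray, n2: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided Fisher p for pairs sharing sample count ``n``.

    Groups pairs by their (min occupancy, max occupancy) margins so the
    hypergeometric pmf over the shared support is computed once per group.
    """
    m1 = np.minimum(n1, n2)
    m2 = np.maximum(n1, n2)
    out = np.empty(a.shape[0], dtype=float)
    order = np.lexsort((m1, m2))
    key = m2[order].astype(np.int64) * (n + 1) + m1[order]
    starts = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
    bounds = np.r_[starts, key.size]
    for s, e in zip(bounds[:-1], bounds[1:]):
        idx = order[s:e]
        k1, k2 = int(m1[idx[0]]), int(m2[idx[0]])
        lo = max(0, k1 + k2 - n)
        support = np.arange(lo, k1 + 1)
        pmf = hypergeom.pmf(support, n, k1, k2)
        # two-sided p per possible a: sum of pmf values <= pmf[a]
        cum = np.array([pmf[pmf <= p_obs * _REL_EPS].sum() for p_obs in pmf])
        out[idx] = np.minimum(cum[a[idx] - lo], 1.0)
    return out


def all_pairs_test(m: PresenceAbsenceMatrix, alpha: float = 0.05) -> list[PairTestResult]:
    """Fisher-test every unordered fragment pair and BH-adjust across all pairs.

    Returns exactly n(n-1)/2 results in row-major upper-triangle order;
    a pair is significant when its adjusted p-value is below ``alpha``.
    """
    if m.n_fragments < 2:
        raise ValidationError("need at least two fragments to test pairs")
    occ = m.occupancy
    n = m.n_samples
    iu, ju, a = _pair_arrays(m.values)
    p_raw = _two_sided_pvalues(a, occ[iu], occ[ju], n)
    p_adj = bh_adjust(p_raw)
    frags = m.fragment_ids
    results = []
    for k in range(iu.size):
        i, j = int(iu[k]), int(ju[k])
        ak = int(a[k])
        b = int(occ[i]) - ak
        c = int(occ[j]) - ak
        results.append(
            PairTestResult(
                fragment_1=frags[i],
                fragment_2=frags[j],
                table=ContingencyTable2x2(ak, b, c, n - ak - b - c),
                p_raw=float(p_raw[k]),
                p_adj=float(p_adj[k]),
                significant=bool(p_adj[k] < alpha),
            )
        )
    return results


def _significant_count(values: np.ndarray, n: int, alpha: float) -> int:
    """Number of significant pairs (full Fisher+BH pipeline) for a raw array."""
    occ = values.sum(axis=1, dtype=np.int64)
    iu, ju, a = _pair_arrays(values)
    p_raw = _two_sided_pvalues(a, occ[iu], occ[ju], n)
    return int(np.sum(bh_adjust(p_raw) < alpha))


# ---------------------------------------------------------------------------
# fixed-margin randomization (null for empirical FDR)


def randomize_fixed_margins(
    m: PresenceAbsenceMatrix,
    seed: int | np.random.Generator,
    method: str = "curveball",
    n_steps: int | None = None,
) -> PresenceAbsenceMatrix:
    """Randomize the matrix while conserving every row and column sum.

    ``curveball`` (default) performs ``n_steps`` pairwise row trades
    (default 5x the number of fragments); ``checkerboard`` attempts
    ``n_steps`` 2x2 submatrix swaps (default 4x the number of presence cells).
    Both samplers leave the margin vectors exactly invariant on every draw.
    """
    rng = np.random.default_rng(seed)
    v = m.values.copy()
    if method == "curveball":
        steps = n_steps if n_steps is not None else 5 * m.n_fragments
        _curveball(v, steps, rng)
    elif method == "checkerboard":
        steps = n_steps if n_steps is not None else 4 * int(v.sum())
        _checkerboard(v, steps, rng)
    else:
        raise ValidationError(f"unknown randomization method {method!r}")
    return PresenceAbsenceMatrix(v, m.fragment_ids, m.sample_ids)


def _curveball(v: np.ndarray, n_trades: int, rng: np.random.Generator) -> None:
    n_rows = v.shape[0]
    for _ in range(n_trades):
        r1, r2 = rng.choice(n_rows, size=2, replace=False)
        a, b = v[r1].astype(bool), v[r2].astype(bool)
        only1 = np.flatnonzero(a & ~b)
        only2 = np.flatnonzero(~a & b)
        total = only1.size + only2.size
        if only1.size == 0 or only2.size == 0:
            continue
        pool = np.concatenate([only1, only2])
        rng.shuffle(pool)
        new1, new2 = pool[: only1.size], pool[only1.size :]
        v[r1, only1] = 0
        v[r2, only2] = 0
        v[r1, new1] = 1
        v[r2, new2] = 1


def _checkerboard(v: np.ndarray, n_attempts: int, rng: np.random.Generator) -> None:
    n_rows, n_cols = v.shape
    rows = rng.integers(0, n_rows, size=(n_attempts, 2))
    cols = rng.integers(0, n_cols, size=(n_attempts, 2))
    for (r1, r2), (c1, c2) in zip(rows, cols):
        if r1 == r2 or c1 == c2:
            continue
        x11, x12, x21, x22 = v[r1, c1], v[r1, c2], v[r2, c1], v[r2, c2]
        if x11 == x22 and x12 == x21 and x11 != x12:
            v[r1, c1], v[r1, c2] = x12, x11
            v[r2, c1], v[r2, c2] = x22, x21


def estimate_fdr(
    m: PresenceAbsenceMatrix,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    method: str = "curveball",
) -> FdrEstimate:
    """Empirical FDR: mean significant count on fixed-margin nulls / observed.

    The full decision pipeline (Fisher on all pairs, BH adjustment, alpha
    threshold) is re-run on each of ``n_reps`` independent randomizations.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _significant_count(m.values, m.n_samples, alpha)
    null_counts = []
    for _ in range(n_reps):
        null = randomize_fixed_margins(m, rng, method=method)
        null_counts.append(_significant_count(null.values, m.n_samples, alpha))
    mean_null = float(np.mean(null_counts))
    fdr = mean_null / observed if observed > 0 else 0.0
    return FdrEstimate(mean_null, fdr, observed, tuple(null_counts))


# ---------------------------------------------------------------------------
# sign classification (occupancy-preserving null)


def classify_sign(
    m: PresenceAbsenceMatrix,
    results: Sequence[PairTestResult],
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> list[PairTestResult]:
    """Classify significant pairs as positive / negative against a permutation null.

    The null permutes each fragment's presence row independently across
    samples, conserving its total occupancy; the resulting co-occurrence
    count of a pair with occupancies (n_A, n_B) over S samples is exactly
    Hypergeometric(S, n_A, n_B), which is sampled directly. A pair is
    positive when the fraction of null draws strictly below the observed
    count (ties counted half) exceeds ``level``, negative when the fraction
    strictly above exceeds ``level``, otherwise unclassified. Non-significant
    pairs are passed through unchanged (sign stays unclassified).
    """
    rng = np.random.default_rng(seed)
    S = m.n_samples
    out: list[PairTestResult] = []
    for r in results:
        if not r.significant:
            out.append(r)
            continue
        n_a = r.table.a + r.table.b
        n_b = r.table.a + r.table.c
        draws = rng.hypergeometric(n_a, S - n_a, n_b, size=n_reps)
        obs = r.table.a
        p_below = (np.sum(draws < obs) + 0.5 * np.sum(draws == obs)) / n_reps
        p_above = (np.sum(draws > obs) + 0.5 * np.sum(draws == obs)) / n_reps
        sign = POSITIVE if p_below > level else NEGATIVE if p_above > level else UNCLASSIFIED
        out.append(replace(r, sign=sign, expected_cooccurrence=float(draws.mean())))
    return out


# ---------------------------------------------------------------------------
# summary panel


def summarize(
    results: Sequence[PairTestResult],
    annotations: Mapping[str, FragmentAnnotation],
    n_fragments: int | None = None,
    fdr: FdrEstimate | None = None,
) -> CooccurrenceSummary:
    """Tabulate correlated-pair counts with bacterial/archaeal breakdowns."""
    fragments = {f for r in results for f in (r.fragment_1, r.fragment_2)}
    missing = sorted(f for f in fragments if f not in annotations)
    if missing:
        raise ValidationError(f"fragments without domain annotation: {missing[:10]}")
    if n_fragments is None:
        n_fragments = len(fragments)
    n_bact = sum(1 for f in fragments if annotations[f].domain == BACTERIAL)
    n_arch = sum(1 for f in fragments if annotations[f].domain == ARCHAEAL)

    sig = [r for r in results if r.significant]
    counts = {
        ("bacterial_pair", POSITIVE): 0, ("bacterial_pair", NEGATIVE): 0,
        ("bacterial_pair", UNCLASSIFIED): 0,
        ("archaeal_pair", POSITIVE): 0, ("archaeal_pair", NEGATIVE): 0,
        ("archaeal_pair", UNCLASSIFIED): 0,
        ("mixed_pair", POSITIVE): 0, ("mixed_pair", NEGATIVE): 0,
        ("mixed_pair", UNCLASSIFIED): 0,
    }
    for r in sig:
        d1 = annotations[r.fragment_1].domain
        d2 = annotations[r.fragment_2].domain
        kind = (
            "bacterial_pair" if d1 == d2 == BACTERIAL
            else "archaeal_pair" if d1 == d2 == ARCHAEAL
            else "mixed_pair"
        )
        counts[(kind, r.sign)] += 1

    def tot(kind: str) -> int:
        return sum(counts[(kind, s)] for s in (POSITIVE, NEGATIVE, UNCLASSIFIED))

    return CooccurrenceSummary(
        n_fragments=n_fragments,
        n_bacterial=n_bact,
        n_archaeal=n_arch,
        n_potential_pairs=potential_pairs(n_fragments),
        n_correlated=len(sig),
        n_positive=sum(1 for r in sig if r.sign == POSITIVE),
        n_negative=sum(1 for r in sig if r.sign == NEGATIVE),
        n_bacterial_pairs=tot("bacterial_pair"),
        n_bacterial_pos=counts[("bacterial_pair", POSITIVE)],
        n_bacterial_neg=counts[("bacterial_pair", NEGATIVE)],
        n_archaeal_pairs=tot("archaeal_pair"),
        n_archaeal_pos=counts[("archaeal_pair", POSITIVE)],
        n_archaeal_neg=counts[("archaeal_pair", NEGATIVE)],
        n_mixed_pairs=tot("mixed_pair"),
        n_mixed_pos=counts[("mixed_pair", POSITIVE)],
        n_mixed_neg=counts[("mixed_pair", NEGATIVE)],
        randomized_mean_correlated=fdr.mean_null_significant if fdr else None,
        estimated_fdr=fdr.estimated_fdr if fdr else None,
    )


def results_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    """Results table: one row per pair with counts, p-values, sign."""
    rows = [
        {
            "fragment_1": r.fragment_1,
            "fragment_2": r.fragment_2,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "significant": r.significant,
            "sign": r.sign,
            "expected_cooccurrence": r.expected_cooccurrence,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["fragment_1", "fragment_2", "a", "b", "c", "d", "p_raw", "p_adj",
                 "significant", "sign", "expected_cooccurrence"],
    )
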