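"""Minimum-hypergeometric (mHG) gene-set enrichment on in-trans rankings.

Given a ranked gene universe of size N and a gene set with B members present
in the universe, the mHG score is

    s = min over prefixes n = 1..N-1 of HGT(b(n); N, B, n)

where b(n) counts members in the top n genes and HGT(b; N, B, n) = P(X >= b)
for hypergeometric X (b successes drawn in n draws from N items of which B
are successes).  Because the minimisation biases s downward, an exact p-value
P(score <= s) under uniform permutation of the member labels is computed by
dynamic programming over the (n, b) lattice, counting the probability mass of
label arrangements whose prefix path avoids the rejection region
R(s) = {(n, b): HGT(b; N, B, n) <= s}.  The DP runs in O(N * B).

Enrichment is evaluated separately for the top and the bottom of each
ranking (the bottom direction scores the reversed list).  Associations are
screened by Bonferroni correction over all (pivot, set, direction) tests and
then called against an empirical null obtained by shuffling the sample order
of the residual expression matrix only, which preserves inter-gene
expression dependencies: an association is significant only if its observed
enrichment beats every null score seen for that gene set across all pivots
and simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cistrans import trans_ranking
from .datamodel import DEFAULT_MIN_PAIRS, GeneSetCollection, GeneTable

logger = logging.getLogger("ipac.enrichment")

#: Relative tolerance for "tail value <= score" comparisons, so that cells
#: whose tails are mathematically equal to the attained minimum are included
#: in the rejection region even if floating summation orders differ.
_REGION_RTOL = 1e-12

DIRECTIONS = ("top", "bottom")


# ---------------------------------------------------------------------------
# Hypergeometric tails (log space)
# ---------------------------------------------------------------------------

def _log_hyper_pmf(k: np.ndarray, n: np.ndarray, B: int, N: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, B, n); -inf outside support."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (gammaln(B + 1) - gammaln(k + 1) - gammaln(B - k + 1)
               + gammaln(N - B + 1) - gammaln(n - k + 1)
               - gammaln(N - B - n + k + 1)
               - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))
    bad = (k < 0) | (k > B) | (k > n) | (n - k > N - B)
    return np.where(bad, -np.inf, out)


def hypergeometric_tail(b: int, n: int, B: int, N: int) -> float:
    """Upper tail P(X >= b) for X ~ Hypergeometric(N, B, n), in log space.

    Parameters follow the draw picture: N items, B marked, n drawn, b or
    more marked among the drawn.
    """
    if not (0 <= b <= n <= N and b <= B <= N):
        raise ValueError(f"invalid hypergeometric parameters "
                         f"b={b}, n={n}, B={B}, N={N}")
    if b == 0:
        return 1.0
    ks = np.arange(b, min(n, B) + 1)
    if len(ks) == 0:
        return 0.0
    return float(np.exp(logsumexp(_log_hyper_pmf(ks, n, B, N))))


def _hgt_table(N: int, B: int) -> np.ndarray:
    """HGT(b; N, B, n) for all n in 0..N-1 and b in 0..B, shape (N, B+1).

    Row n holds the upper tails after n draws; row 0 is all ones.  Built from
    log-space pmfs with a reverse cumulative sum, O(N * B) memory.
    """
    table = np.ones((N, B + 1))
    n = np.arange(1, N)[:, None]
    k = np.arange(B + 1)[None, :]
    pmf = np.exp(_log_hyper_pmf(np.broadcast_to(k, (N - 1, B + 1)),
                                np.broadcast_to(n, (N - 1, B + 1)), B, N))
    tails = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    table[1:] = np.minimum(tails, 1.0)
    table[:, 0] = 1.0
    return table


# ---------------------------------------------------------------------------
# mHG score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MhgResult:
    """mHG score with the optimal prefix and its fold enrichment."""

    score: float
    n_star: int
    b_star: int
    fold: float
    N: int
    B: int
    p_exact: float | None = None


def mhg_score(labels: np.ndarray) -> MhgResult:
    """mHG score of a binary vector in ranking order (1 = set member).

    The minimum is taken over prefixes 1..N-1; n_star is the smallest prefix
    attaining it.  B = 0 gives score 1 by convention.
    """
    labels = np.asarray(labels, dtype=int)
    N = len(labels)
    if N < 2:
        raise ValueError("need a list of length >= 2")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    B = int(labels.sum())
    if B == 0:
        return MhgResult(score=1.0, n_star=1, b_star=0, fold=np.nan, N=N, B=B)
    table = _hgt_table(N, B)
    positions = np.flatnonzero(labels) + 1          # 1-based prefix ends
    return _score_from_positions(positions, table, N, B)


def _score_from_positions(positions: np.ndarray, table: np.ndarray,
                          N: int, B: int) -> MhgResult:
    """Score from sorted 1-based member positions via the HGT table.

    The prefix minimum only needs checking at prefixes ending in a member:
    HGT(b; N, B, n) is strictly increasing in n at fixed b, so a longer
    prefix with the same member count can never attain a smaller tail.
    """
    bs = np.arange(1, len(positions) + 1)
    valid = positions < N                            # prefixes must have n < N
    if not valid.any():
        return MhgResult(score=1.0, n_star=1, b_star=0, fold=np.nan, N=N, B=B)
    ns = positions[valid]
    bs = bs[valid]
    vals = table[ns, bs]
    j = int(np.argmin(vals))                         # first minimum => smallest n
    return MhgResult(score=float(vals[j]), n_star=int(ns[j]), b_star=int(bs[j]),
                     fold=float((bs[j] / ns[j]) / (B / N)), N=N, B=B)


# ---------------------------------------------------------------------------
# Exact mHG p-value (lattice DP)
# ---------------------------------------------------------------------------

def mhg_pvalue_batch(scores: np.ndarray, N: int, B: int,
                     table: np.ndarray | None = None) -> np.ndarray:
    """Exact P(mHG score <= s) for several scores sharing (N, B).

    One DP pass over the (n, b) lattice serves all scores: pi[b, q] is the
    probability that a uniformly random arrangement reaches (n, b) without
    having entered the rejection region of score q.  Mass entering the region
    is accumulated directly, which keeps tiny p-values accurate (no 1 - x
    cancellation).
    """
    scores = np.asarray(scores, dtype=float)
    if B == 0:
        return np.ones_like(scores)
    if table is None:
        table = _hgt_table(N, B)
    uniq, inverse = np.unique(scores, return_inverse=True)
    thresholds = uniq * (1.0 + _REGION_RTOL)
    nq = len(uniq)
    pi = np.zeros((B + 1, nq))
    pi[0, :] = 1.0
    new = np.empty_like(pi)
    scratch = np.empty_like(pi)
    p_acc = np.zeros(nq)
    num = (B - np.arange(B + 1, dtype=float))[:, None]   # members left at count b
    bvals = np.arange(B + 1)[:, None]
    for n in range(1, N):
        # transition from n-1 to n: draw a member with prob (B-b)/(N-n+1)
        np.multiply(pi, num / (N - n + 1), out=scratch)   # mass moving b -> b+1
        np.subtract(pi, scratch, out=new)
        new[1:, :] += scratch[:-1, :]
        # the region at prefix n is an upper set in b (HGT decreases in b):
        # absorb and zero all cells with b >= b_min(n, q)
        row = table[n]                                    # decreasing in b
        b_min = (B + 1) - np.searchsorted(row[::-1], thresholds, side="right")
        in_region = bvals >= b_min[None, :]
        p_acc += np.where(in_region, new, 0.0).sum(axis=0)
        new[in_region] = 0.0
        pi, new = new, pi
    # clip into the analytic bounds s <= p <= min(1, N*s)
    p = np.minimum(np.maximum(p_acc, uniq), np.minimum(1.0, N * uniq))
    return p[inverse].reshape(scores.shape)


def mhg_pvalue(score: float, N: int, B: int) -> float:
    """Exact p-value of one mHG score (see :func:`mhg_pvalue_batch`)."""
    if not 0 < score <= 1:
        raise ValueError("score must be in (0, 1]")
    if N < 2 or not 0 <= B <= N:
        raise ValueError("invalid N, B")
    return float(mhg_pvalue_batch(np.array([score]), N, B)[0])


# ---------------------------------------------------------------------------
# Enricher: fixed universe + gene sets, scored against many rankings
# ---------------------------------------------------------------------------

class Enricher:
    """Pre-indexes gene sets against a fixed gene universe for fast scoring.

    Sets are intersected with the universe; those with fewer than
    ``min_size`` or more than ``max_size`` members in the universe are
    skipped (logged).  Sets sharing a member count B share one HGT table and
    one batched p-value DP.
    """

    def __init__(self, universe: list[str], sets: GeneSetCollection,
                 min_size: int = 3, max_size: int = 2000):
        self.universe = list(universe)
        self.N = len(self.universe)
        index = {g: i for i, g in enumerate(self.universe)}
        self.set_ids: list[str] = []
        self.members: dict[str, np.ndarray] = {}
        skipped = []
        for set_id, (name, members) in sorted(sets):
            idx = np.array(sorted(index[m] for m in members if m in index),
                           dtype=int)
            if not min_size <= len(idx) <= max_size:
                skipped.append(set_id)
                continue
            self.set_ids.append(set_id)
            self.members[set_id] = idx
        if skipped:
            logger.info("skipping %d gene sets outside size bounds [%d, %d] "
                        "in a universe of %d genes",
                        len(skipped), min_size, max_size, self.N)
        self.B: dict[str, int] = {s: len(self.members[s]) for s in self.set_ids}
        self._tables: dict[int, np.ndarray] = {}
        # group sets by B so scoring and p-value DPs are batched
        self._by_B: dict[int, list[str]] = {}
        for s in self.set_ids:
            self._by_B.setdefault(self.B[s], []).append(s)
        self._member_matrix: dict[int, np.ndarray] = {
            B: np.vstack([self.members[s] for s in ids])
            for B, ids in self._by_B.items()}

    def _table(self, B: int) -> np.ndarray:
        if B not in self._tables:
            self._tables[B] = _hgt_table(self.N, B)
        return self._tables[B]

    def score_batch(self, rank_of: np.ndarray, B: int) -> np.ndarray:
        """Scores of all sets with ``B`` members, given gene ranks.

        ``rank_of[i]`` is the rank (0 = best) of universe gene i.  Scores only
        (no optimal prefix); used in the empirical-null inner loop.
        """
        table = self._table(B)
        pos = np.sort(rank_of[self._member_matrix[B]], axis=1) + 1
        bs = np.arange(1, B + 1)
        vals = table[np.minimum(pos, self.N - 1), bs[None, :]]
        vals = np.where(pos < self.N, vals, np.inf)
        scores = vals.min(axis=1)
        return np.where(np.isfinite(scores), scores, 1.0)

    def score_order(self, order: np.ndarray) -> dict[str, MhgResult]:
        """mHG scores of all sets against one ranking.

        ``order`` is an array of universe indices in rank order (best first).
        """
        if len(order) != self.N:
            raise ValueError("ranking does not cover the full universe")
        rank_of = np.empty(self.N, dtype=int)
        rank_of[order] = np.arange(self.N)
        out: dict[str, MhgResult] = {}
        for B, set_ids in self._by_B.items():
            table = self._table(B)
            # (n_sets, B) member positions per ranking, evaluated in one go
            pos = np.sort(rank_of[self._member_matrix[B]], axis=1) + 1
            bs = np.arange(1, B + 1)
            vals = table[np.minimum(pos, self.N - 1), bs[None, :]]
            vals = np.where(pos < self.N, vals, np.inf)  # prefixes need n < N
            j = np.argmin(vals, axis=1)                  # first min => smallest n
            rows = np.arange(len(set_ids))
            score = vals[rows, j]
            n_star, b_star = pos[rows, j], bs[j]
            for i, s in enumerate(set_ids):
                if not np.isfinite(score[i]):
                    out[s] = MhgResult(score=1.0, n_star=1, b_star=0,
                                       fold=np.nan, N=self.N, B=B)
                else:
                    out[s] = MhgResult(
                        score=float(score[i]), n_star=int(n_star[i]),
                        b_star=int(b_star[i]),
                        fold=float((b_star[i] / n_star[i]) / (B / self.N)),
                        N=self.N, B=B)
        return out

    def pvalues(self, results: dict[str, MhgResult]) -> dict[str, float]:
        """Exact p-values for per-set score results, batched per B."""
        out: dict[str, float] = {}
        for B, set_ids in self._by_B.items():
            ids = [s for s in set_ids if s in results]
            if not ids:
                continue
            scores = np.array([results[s].score for s in ids])
            ps = mhg_pvalue_batch(scores, self.N, B, self._table(B))
            out.update(zip(ids, ps))
        return out

    def pvalues_frame(self, records: pd.DataFrame) -> np.ndarray:
        """Exact p-values for a whole records table in one DP per member
        count; duplicate scores (across pivots and directions) are collapsed
        inside the batch."""
        out = np.full(len(records), np.nan)
        b_of = records["set_id"].map(self.B).to_numpy()
        scores = records["mhg_score"].to_numpy()
        for B in self._by_B:
            mask = b_of == B
            if mask.any():
                out[mask] = mhg_pvalue_batch(scores[mask], self.N, B,
                                             self._table(B))
        return out


def _ranking_order(ranking, universe_index: dict[str, int]) -> np.ndarray:
    return np.fromiter((universe_index[g] for g in ranking.genes),
                       dtype=int, count=len(ranking.genes))


def enrich_pivot(ranking, sets: GeneSetCollection, direction: str = "top",
                 min_size: int = 3, max_size: int = 2000,
                 enricher: Enricher | None = None,
                 compute_p: bool = True) -> pd.DataFrame:
    """Score every gene set against one pivot's ranking in one direction.

    The bottom direction evaluates the reversed ranking.  Returns one record
    per set with the score, optimal prefix, fold enrichment and exact
    p-value; sets outside the size bounds are skipped.  With
    ``compute_p=False`` the p_exact column is left NaN so a caller scoring
    many pivots can batch all p-values at the end
    (:meth:`Enricher.pvalues_frame`).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if enricher is None:
        enricher = Enricher(ranking.genes, sets, min_size, max_size)
    index = {g: i for i, g in enumerate(enricher.universe)}
    order = _ranking_order(ranking, index)
    if direction == "bottom":
        order = order[::-1]
    results = enricher.score_order(order)
    pvals = enricher.pvalues(results) if compute_p else {}
    rows = []
    for set_id in enricher.set_ids:
        r = results[set_id]
        rows.append((ranking.pivot, set_id, direction, r.score,
                     pvals.get(set_id, np.nan), r.n_star, r.b_star, r.fold,
                     enricher.N, r.B))
    return pd.DataFrame(rows, columns=["pivot", "set_id", "direction",
                                       "mhg_score", "p_exact", "n_star",
                                       "b_star", "fold", "N", "B"])


# ---------------------------------------------------------------------------
# Bonferroni screening, empirical null, final calls
# ---------------------------------------------------------------------------

def bonferroni_filter(records: pd.DataFrame, alpha: float = 0.05,
                      n_tests: int | None = None) -> pd.DataFrame:
    """Flag records with p_exact * n_tests < alpha (strict).

    The default family is every potential association actually tested:
    n_pivots x n_sets x 2 directions, counted from the records themselves.
    """
    records = records.copy()
    if n_tests is None:
        n_tests = (records["pivot"].nunique() * records["set_id"].nunique()
                   * records["direction"].nunique())
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    records["bonferroni_pass"] = records["p_exact"] * n_tests < alpha
    records.attrs["n_tests"] = n_tests
    return records


@dataclass
class NullScoreStore:
    """Per-set minima of enrichment over all pivots and null simulations.

    ``min_score[direction][set_id]`` is the smallest mHG score seen for that
    set under the sample-shuffle null; ``p_star[direction][set_id]`` is its
    exact p-value (the p-value is strictly increasing in the score at fixed
    N and B, so score minima and p-value minima coincide).
    """

    min_score: dict[str, dict[str, float]]
    p_star: dict[str, dict[str, float]]
    n_sims: int
    seed: int | None = None


def empirical_null(residuals: pd.DataFrame, pivots: list[str],
                   expr: pd.DataFrame, sets: GeneSetCollection,
                   n_sims: int = 100, seed: int | np.random.Generator = 0,
                   min_size: int = 3, max_size: int = 2000,
                   min_pairs: int | None = None,
                   enricher: Enricher | None = None,
                   identity_permutation: bool = False) -> NullScoreStore:
    """Sample-shuffle empirical null for all (pivot, set, direction) tests.

    Per simulation one random permutation of the residual-matrix sample
    columns is drawn (shared by all pivots; pivot expression is never
    permuted), every pivot's ranking is recomputed and every set rescored;
    the minimum score per set and direction across all pivots and
    simulations is retained.  Permuting the residual columns against a fixed
    pivot vector equals correlating the inverse-permuted pivot vector with
    the unpermuted residuals, which is how it is computed.

    ``identity_permutation`` forces the identity in every simulation (for
    degenerate checks only).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if min_pairs is None:
        min_pairs = DEFAULT_MIN_PAIRS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = [str(g) for g in residuals.index]
    if enricher is None:
        enricher = Enricher(universe, sets, min_size, max_size)
    if list(enricher.universe) != universe:
        raise ValueError("enricher universe does not match the residual matrix")
    from .cistrans import _rowwise_pearson
    n_samples = residuals.shape[1]
    R = residuals.to_numpy(dtype=float)
    names = np.asarray(universe)
    pivot_rows = {p: expr.index.get_loc(p) for p in pivots}
    E = expr.to_numpy(dtype=float)

    best_arr = {d: {B: np.full(len(ids), np.inf)
                    for B, ids in enricher._by_B.items()} for d in DIRECTIONS}
    for k in range(n_sims):
        perm = (np.arange(n_samples) if identity_permutation
                else rng.permutation(n_samples))
        inv = np.argsort(perm)
        for pivot in pivots:
            e = E[pivot_rows[pivot]][inv]
            r = _rowwise_pearson(R, np.broadcast_to(e, R.shape), min_pairs)
            r = np.nan_to_num(r, nan=0.0)
            order = np.lexsort((names, -r))
            for direction, o in (("top", order), ("bottom", order[::-1])):
                rank_of = np.empty(enricher.N, dtype=int)
                rank_of[o] = np.arange(enricher.N)
                for B in enricher._by_B:
                    scores = enricher.score_batch(rank_of, B)
                    np.minimum(best_arr[direction][B], scores,
                               out=best_arr[direction][B])
    best: dict[str, dict[str, float]] = {d: {} for d in DIRECTIONS}
    p_star: dict[str, dict[str, float]] = {d: {} for d in DIRECTIONS}
    for direction in DIRECTIONS:
        for B, ids in enricher._by_B.items():
            scores = best_arr[direction][B]
            ps = mhg_pvalue_batch(scores, enricher.N, B, enricher._table(B))
            for s, sc, p in zip(ids, scores, ps):
                best[direction][s] = float(sc)
                p_star[direction][s] = float(p)
    return NullScoreStore(min_score=best, p_star=p_star, n_sims=n_sims,
                          seed=None if isinstance(seed, np.random.Generator)
                          else int(seed))


def call_ipac(records: pd.DataFrame, null_store: NullScoreStore
              ) -> tuple[pd.DataFrame, list[str]]:
    """Final calls: significant iff Bonferroni passes and the observed score
    beats every null score for the set (strict).

    Adds ``empirical_significant`` and the Table-1-style
    ``signed_log_score`` (-log10 p, negative for bottom-direction
    associations); returns the annotated records and the list of pivot genes
    with at least one significant association (the iPAC genes).
    """
    if "bonferroni_pass" not in records.columns:
        raise ValueError("records must be Bonferroni-filtered first")
    records = records.copy()
    sig = np.zeros(len(records), dtype=bool)
    scores = records["mhg_score"].to_numpy()
    for i, (set_id, direction, bonf) in enumerate(
            zip(records["set_id"], records["direction"],
                records["bonferroni_pass"])):
        if not bonf:
            continue
        s_star = null_store.min_score[direction].get(set_id, np.inf)
        sig[i] = scores[i] < s_star
    records["empirical_significant"] = sig
    with np.errstate(divide="ignore"):
        logp = -np.log10(records["p_exact"].to_numpy())
    records["signed_log_score"] = np.where(records["direction"] == "bottom",
                                           -logp, logp)
    ipac_genes = sorted(records.loc[sig, "pivot"].unique())
    logger.info("iPAC calls: %d significant associations over %d genes",
                int(sig.sum()), len(ipac_genes))
    return records, ipac_genes


# ---------------------------------------------------------------------------
# Cross-cohort consistency
# ---------------------------------------------------------------------------

def cross_cohort_consistency(pairs: pd.DataFrame, cohort2: GeneTable,
                             sets: GeneSetCollection, n_random: int = 100,
                             seed: int | np.random.Generator = 0,
                             min_size: int = 3, max_size: int = 2000,
                             min_pairs: int | None = None) -> pd.DataFrame:
    """Re-score (gene, set, direction) associations in a second cohort.

    The second cohort is processed through its own cis fits and residuals;
    each pair's signed log score is compared with the scores of ``n_random``
    random pivot genes for the same set, reported as a z-score
    (score - mean_background) / sd_background.  Pairs whose gene is absent
    from the second cohort are skipped with a log entry; zero-variance
    backgrounds give a NaN z with a flag.
    """
    from .cistrans import residual_matrix
    if min_pairs is None:
        min_pairs = DEFAULT_MIN_PAIRS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit = residual_matrix(cohort2, min_pairs)
    universe = [str(g) for g in cohort2.expr.index]
    enricher = Enricher(universe, sets, min_size, max_size)
    index = {g: i for i, g in enumerate(enricher.universe)}

    random_pivots = list(rng.choice(universe, size=min(n_random, len(universe)),
                                    replace=False))
    # background rankings computed once, shared across pairs
    bg_results: dict[str, dict[str, dict[str, MhgResult]]] = {d: {} for d in DIRECTIONS}
    for g in random_pivots:
        ranking = trans_ranking(g, cohort2.expr, fit.residuals, min_pairs=min_pairs)
        order = _ranking_order(ranking, index)
        bg_results["top"][g] = enricher.score_order(order)
        bg_results["bottom"][g] = enricher.score_order(order[::-1])

    rows = []
    cache: dict[str, dict[str, dict[str, MhgResult]]] = {}
    for gene, set_id, direction in pairs[["pivot", "set_id", "direction"]
                                         ].itertuples(index=False):
        if gene not in cohort2.expr.index:
            logger.warning("gene %s absent from second cohort; pair skipped", gene)
            continue
        if set_id not in enricher.members:
            logger.warning("set %s outside size bounds in second cohort; "
                           "pair skipped", set_id)
            continue
        if gene not in cache:
            ranking = trans_ranking(gene, cohort2.expr, fit.residuals,
                                    min_pairs=min_pairs)
            order = _ranking_order(ranking, index)
            cache[gene] = {"top": enricher.score_order(order),
                           "bottom": enricher.score_order(order[::-1])}
        res = cache[gene][direction][set_id]
        B = enricher.B[set_id]
        table = enricher._table(B)
        obs_p = float(mhg_pvalue_batch(np.array([res.score]), enricher.N, B,
                                       table)[0])
        bg_scores = np.array([bg_results[direction][g][set_id].score
                              for g in random_pivots])
        bg_p = mhg_pvalue_batch(bg_scores, enricher.N, B, table)
        sign = -1.0 if direction == "bottom" else 1.0
        obs_log = sign * -np.log10(obs_p)
        bg_log = sign * -np.log10(bg_p)
        mu, sd = float(bg_log.mean()), float(bg_log.std(ddof=1))
        if sd <= 0:
            logger.warning("zero-variance background for set %s; z undefined",
                           set_id)
            z = np.nan
        else:
            z = (obs_log - mu) / sd
        rows.append((gene, set_id, direction, obs_log, mu, sd, z, sd > 0))
    return pd.DataFrame(rows, columns=["pivot", "set_id", "direction",
                                       "signed_log_score", "background_mean",
                                       "background_sd", "z", "z_defined"])
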