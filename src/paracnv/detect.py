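"""Two-group differential read-count testing: the negative-binomial exact
test, common-dispersion estimation, BH FDR control and the mapping-option
consensus rule.

Model
-----
Counts for gene *g* in individual *i* are negative binomial with mean
``mu_gi`` and variance ``mu_gi + phi * mu_gi**2``; a single common
dispersion ``phi`` is shared by all genes (``phi = 0`` degenerates to
Poisson).  After library sizes are equalized by proportional scaling to the
geometric-mean library size (rounded to integer pseudo-counts), the group
sums ``A = sum_{i in A} y_gi`` and ``B`` are themselves negative binomial
(sum of n iid NB(r, p) is NB(n*r, p) with ``r = 1/phi``), and the
conditional law of ``A`` given ``N = A + B`` is beta-binomial
``BetaBin(N, a=n_A/phi, b=n_B/phi)`` — independent of the common mean.  The
exact test sums, over all splits ``(a, N-a)``, the probabilities that do not
exceed the probability of the observed split (minimum-likelihood two-sided
rule); in the Poisson limit this is the conditional binomial test.

Multiple testing is controlled by the Benjamini–Hochberg step-up procedure,
and a gene is called a consensus copy-number variant only when its FDR is
below ``alpha`` under every supplied mapping-stringency replicate with a
consistent direction of change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .counting import CountMatrix, filter_genes, normalize

__all__ = [
    "DispersionEstimate",
    "DetectionOutput",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "exact_test_batch",
    "bh_fdr",
    "consensus_gcnvs",
    "run_detection",
]

logger = logging.getLogger(__name__)

#: relative tolerance for the "probability not larger than observed" tie rule,
#: the convention used by R's binom.test and scipy's binomtest
_TIE_RTOL = 1.0 + 1e-7

#: dispersion values below this are reported as exactly Poisson
_PHI_FLOOR = 2e-6

_PHI_MAX = 10.0


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi (variance = mu + phi * mu^2); phi >= 0."""

    phi: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# library-size equalization
# ---------------------------------------------------------------------------


def equalize_library_sizes(
    counts: np.ndarray, totals: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale each sample's counts to the geometric-mean library size.

    Returns integer pseudo-counts (rounded to nearest) and the common
    library size.  After equalization all samples are treated as having the
    same library size, which is what makes the conditional exact test valid.
    """
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(totals))))
    pseudo = np.rint(np.asarray(counts) * (common / totals)[None, :]).astype(np.int64)
    return pseudo, common


# ---------------------------------------------------------------------------
# common-dispersion estimation (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _group_cond_loglik(pseudo: np.ndarray, masks: Sequence[np.ndarray], phi: float) -> float:
    """Log-likelihood of within-group splits conditional on group totals.

    For one group of n samples with counts y_1..y_n summing to z the
    conditional probability under iid NB(r=1/phi) is
    ``prod_i C(y_i + r - 1, y_i) / C(z + n*r - 1, z)``; terms constant in
    phi are dropped.
    """
    r = 1.0 / phi
    ll = 0.0
    for mask in masks:
        y = pseudo[:, mask]
        n = y.shape[1]
        z = y.sum(axis=1)
        g = y.shape[0]
        ll += (
            gammaln(y + r).sum()
            - g * n * gammaln(r)
            + g * gammaln(n * r)
            - gammaln(z + n * r).sum()
        )
    return float(ll)


def estimate_common_dispersion(
    matrix: CountMatrix | np.ndarray,
    groups: tuple[str, str] | None = None,
    *,
    masks: Sequence[np.ndarray] | None = None,
    totals: np.ndarray | None = None,
) -> DispersionEstimate:
    """Maximize the conditional NB log-likelihood over phi in [0, 10].

    Accepts either a :class:`CountMatrix` (with ``groups`` naming the two
    group labels, inferred when omitted) or a raw pseudo-count array with
    explicit boolean ``masks``.  Counts are library-size equalized first
    unless a raw array is given (then it must already be equalized).
    The search is bracketed on [0, 10] with tolerance 1e-6; estimates below
    2e-6 are reported as exactly 0 (Poisson).
    """
    if isinstance(matrix, CountMatrix):
        if groups is None:
            labels = list(dict.fromkeys(matrix.groups))
            if len(labels) != 2:
                raise ValueError(f"need exactly two groups, found {labels}")
            groups = (labels[0], labels[1])
        masks = [matrix.group_mask(g) for g in groups]
        for g, m in zip(groups, masks):
            if m.sum() < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        pseudo, _ = equalize_library_sizes(matrix.counts, matrix.totals)
    else:
        pseudo = np.asarray(matrix)
        if masks is None:
            raise ValueError("raw-array input requires masks")
        if totals is not None:
            pseudo, _ = equalize_library_sizes(pseudo, totals)
    if pseudo.sum() == 0:
        raise ValueError("all-zero count matrix")

    def neg(phi: float) -> float:
        return -_group_cond_loglik(pseudo, masks, phi)

    res = optimize.minimize_scalar(
        neg, bounds=(1e-8, _PHI_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(res.x)
    if phi < _PHI_FLOOR:
        phi = 0.0
    return DispersionEstimate(phi=phi)


# ---------------------------------------------------------------------------
# the exact test
# ---------------------------------------------------------------------------


def _split_logpmf(N: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log-probability of every split (k, N-k) of the conditional total."""
    k = np.arange(N + 1)
    if phi == 0.0:
        return stats.binom.logpmf(k, N, n_a / (n_a + n_b))
    r_a, r_b = n_a / phi, n_b / phi
    return stats.betabinom.logpmf(k, N, r_a, r_b)


def nb_exact_test(
    count_sum_a: int,
    count_sum_b: int,
    n_a: int,
    n_b: int,
    phi: float | DispersionEstimate,
) -> float:
    """Two-sided NB exact test p-value for library-size-equalized group sums.

    Enumerates all splits ``(k, N-k)`` of ``N = A + B`` and sums the
    probabilities of splits no more probable than the observed one.
    ``phi = 0`` is the Poisson limit (conditional binomial).  Returns
    ``p in (0, 1]``.
    """
    if isinstance(phi, DispersionEstimate):
        phi = phi.phi
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if count_sum_a < 0 or count_sum_b < 0:
        raise ValueError("count sums must be >= 0")
    N = int(count_sum_a) + int(count_sum_b)
    if N == 0:
        return 1.0
    logpmf = _split_logpmf(N, n_a, n_b, phi)
    pmf = np.exp(logpmf - logpmf.max())
    obs = pmf[int(count_sum_a)]
    p = pmf[pmf <= obs * _TIE_RTOL].sum() / pmf.sum()
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


# -- batched path -----------------------------------------------------------


_LFACT = np.zeros(1)  # lgamma(k+1) lookup, grown on demand


def _lfact(n_max: int) -> np.ndarray:
    global _LFACT
    if len(_LFACT) <= n_max:
        _LFACT = gammaln(np.arange(n_max + 1, dtype=np.float64) + 1.0)
    return _LFACT


def _symmetric_bb_left_tail(
    m: np.ndarray, N: np.ndarray, r: float
) -> np.ndarray:
    """P(K <= m) for K ~ BetaBin(N, r, r) (or Binom(N, 1/2) when r=inf),
    vectorized over genes via one flat table-gather evaluation.

    Every gene in one analysis shares ``r``, so the log-pmf of a split is a
    closed form in (k, N) assembled from two integer-indexed lgamma tables.
    Because the pmf is unimodal and m lies left of the mode, terms below
    ``exp(-60)`` of the leading term contribute less than 1e-18 of the tail
    and are skipped (the per-gene lower cut is sized from the normal-curvature
    approximation with a wide safety margin).
    """
    m = np.asarray(m, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    n_max = int(N.max()) if len(N) else 0
    lf = _lfact(n_max + 1)
    var = N / 4.0 if math.isinf(r) else N * (2 * r + N) / (4.0 * (2 * r + 1))
    d = N / 2.0 - m  # distance of m below the (central) mode
    span = 1.5 * (-d + np.sqrt(d * d + 120.0 * var)) + 8.0
    lo = np.maximum(m - span.astype(np.int64), 0)

    sizes = m - lo + 1
    gene_idx = np.repeat(np.arange(len(m)), sizes)
    k = (
        np.arange(sizes.sum())
        - np.repeat(np.cumsum(sizes) - sizes, sizes)
        + lo[gene_idx]
    )
    Nk = N[gene_idx]
    if math.isinf(r):
        lp = lf[Nk] - lf[k] - lf[Nk - k] - Nk * math.log(2.0)
    else:
        tr = gammaln(np.arange(n_max + 1, dtype=np.float64) + r)
        const = lf[N] - gammaln(N + 2 * r) + gammaln(2 * r) - 2 * gammaln(r)
        lp = const[gene_idx] - lf[k] - lf[Nk - k] + tr[k] + tr[Nk - k]
    return np.bincount(gene_idx, weights=np.exp(lp), minlength=len(m))


def _normal_approx_p(a: np.ndarray, N: np.ndarray, n_a: int, n_b: int,
                     phi: float) -> np.ndarray:
    """Normal approximation (with continuity correction) to the two-sided
    conditional test; used only to screen genes inside permutations."""
    p0 = n_a / (n_a + n_b)
    mean = N * p0
    var = N * p0 * (1 - p0)
    if phi > 0:
        s = (n_a + n_b) / phi
        var = var * (s + N) / (s + 1)
    sd = np.sqrt(np.maximum(var, 1e-300))
    z = (np.abs(a - mean) - 0.5) / sd
    return np.minimum(2.0 * stats.norm.sf(np.maximum(z, 0.0)), 1.0)


def exact_test_batch(
    sum_a: np.ndarray,
    sum_b: np.ndarray,
    n_a: int,
    n_b: int,
    phi: float,
    screen_alpha: float | None = None,
) -> np.ndarray:
    """Vectorized two-sided exact test over many genes at once.

    Requires equal group sizes (``n_a == n_b``), where the conditional split
    distribution is symmetric and unimodal so the minimum-likelihood
    two-sided p equals twice the smaller tail.  With ``screen_alpha`` set,
    exact tail sums are computed only for genes whose normal-approximation p
    is below ``3 * screen_alpha``; the rest keep the approximate p, which is
    then guaranteed to exceed ``screen_alpha`` and so cannot change which
    genes fall under a BH threshold at ``screen_alpha``.
    """
    if n_a != n_b:
        return np.array([
            nb_exact_test(a, b, n_a, n_b, phi) for a, b in zip(sum_a, sum_b)
        ])
    if phi < 0:
        raise ValueError("phi must be >= 0")
    r = math.inf if phi == 0.0 else n_a / phi
    if not math.isinf(r) and r <= 1.0:
        # flat or U-shaped conditional pmf; fall back to full enumeration
        return np.array([
            nb_exact_test(a, b, n_a, n_b, phi) for a, b in zip(sum_a, sum_b)
        ])
    sum_a = np.asarray(sum_a, dtype=np.int64)
    sum_b = np.asarray(sum_b, dtype=np.int64)
    N = sum_a + sum_b
    m = np.minimum(sum_a, sum_b)
    p = np.ones(len(N))
    central = 2 * m == N  # the most probable split: p = 1 by symmetry
    todo = ~central & (N > 0)
    if screen_alpha is not None:
        approx = _normal_approx_p(sum_a, N, n_a, n_b, phi)
        exact_mask = todo & (approx < 3.0 * screen_alpha)
        p[todo] = np.maximum(approx[todo], np.nextafter(screen_alpha, 1.0))
        todo = exact_mask
    if todo.any():
        tail = _symmetric_bb_left_tail(m[todo], N[todo], r)
        p[todo] = np.minimum(2.0 * tail, 1.0)
    return np.maximum(p, np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values in the input order.

    ``q_(i) = min_{j >= i}( p_(j) * m / j )`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# per-stringency analysis and consensus
# ---------------------------------------------------------------------------


@dataclass
class DetectionOutput:
    """Detection results over the shared (all-stringency) gene universe."""

    table: pd.DataFrame  # one row per shared-universe gene
    dispersions: dict[str, float]
    filter_logs: dict[str, pd.DataFrame]
    per_stringency: dict[str, pd.DataFrame]
    alpha: float
    group_a: str
    group_b: str

    @property
    def consensus_gene_ids(self) -> list[str]:
        t = self.table
        return t.loc[t.consensus_gcnv, "gene_id"].tolist()


def _analyze_one(
    matrix: CountMatrix, group_a: str, group_b: str
) -> tuple[pd.DataFrame, float]:
    """Filter, normalize and exact-test one stringency's count matrix."""
    filtered, flog = filter_genes(matrix)
    if filtered.n_genes == 0:
        empty = pd.DataFrame(
            columns=["gene_id", "mean_norm_A", "mean_norm_B", "p", "fdr"]
        )
        empty.attrs["filter_log"] = flog
        return empty, 0.0
    normalize(filtered)
    mask_a = filtered.group_mask(group_a)
    mask_b = filtered.group_mask(group_b)
    pseudo, _ = equalize_library_sizes(filtered.counts, filtered.totals)
    phi = estimate_common_dispersion(pseudo, masks=[mask_a, mask_b]).phi
    p = exact_test_batch(
        pseudo[:, mask_a].sum(axis=1),
        pseudo[:, mask_b].sum(axis=1),
        int(mask_a.sum()),
        int(mask_b.sum()),
        phi,
    )
    df = pd.DataFrame(
        {
            "gene_id": filtered.gene_ids,
            "mean_norm_A": filtered.normalized[:, mask_a].mean(axis=1),
            "mean_norm_B": filtered.normalized[:, mask_b].mean(axis=1),
            "p": p,
            "fdr": bh_fdr(p),
        }
    )
    df.attrs["filter_log"] = flog
    return df, phi


def consensus_gcnvs(
    per_stringency: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Intersect per-stringency results into consensus GCNV calls.

    The shared universe is the intersection of each stringency's post-filter
    gene set; a gene is a consensus GCNV iff ``fdr < alpha`` under every
    stringency.  Direction comes from the reference stringency's normalized
    group means and must agree across stringencies, otherwise the gene is
    dropped from the consensus with a warning.
    """
    if not per_stringency:
        raise ValueError("no result sets supplied")
    labels = list(per_stringency)
    reference = reference or labels[0]
    universe: list[str] | None = None
    for lab in labels:
        ids = per_stringency[lab]["gene_id"].tolist()
        if universe is None:
            universe = ids
        else:
            keep = set(ids)
            universe = [g for g in universe if g in keep]
    if not universe:
        raise ValueError("empty shared gene universe across stringencies")

    indexed = {lab: df.set_index("gene_id") for lab, df in per_stringency.items()}
    ref = indexed[reference].loc[universe]
    out = pd.DataFrame(
        {
            "gene_id": universe,
            "mean_norm_A": ref["mean_norm_A"].to_numpy(),
            "mean_norm_B": ref["mean_norm_B"].to_numpy(),
        }
    )
    sig_all = np.ones(len(universe), dtype=bool)
    directions = []
    for lab in labels:
        sub = indexed[lab].loc[universe]
        out[f"p_{lab}"] = sub["p"].to_numpy()
        out[f"fdr_{lab}"] = sub["fdr"].to_numpy()
        # alpha = 1 disables the threshold (BH values are capped at 1)
        out[f"sig_{lab}"] = (
            np.ones(len(universe), dtype=bool) if alpha >= 1
            else sub["fdr"].to_numpy() < alpha
        )
        sig_all &= out[f"sig_{lab}"].to_numpy()
        directions.append(
            np.sign(sub["mean_norm_A"].to_numpy() - sub["mean_norm_B"].to_numpy())
        )
    dir_ref = directions[labels.index(reference)]
    agree = np.ones(len(universe), dtype=bool)
    for d in directions:
        agree &= (d == dir_ref) & (d != 0)
    dropped = sig_all & ~agree
    if dropped.any():
        logger.warning(
            "%d gene(s) significant in all stringencies but with "
            "disagreeing direction were dropped from the consensus: %s",
            int(dropped.sum()),
            ", ".join(np.array(universe)[dropped]),
        )
    out["direction"] = np.where(dir_ref > 0, "increased_in_A", "increased_in_B")
    out["consensus_gcnv"] = sig_all & agree
    return out


def run_detection(
    matrices: Mapping[str, CountMatrix],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    reference: str | None = None,
) -> DetectionOutput:
    """Full detection pass over all mapping-stringency count matrices."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    per_str: dict[str, pd.DataFrame] = {}
    dispersions: dict[str, float] = {}
    filter_logs: dict[str, pd.DataFrame] = {}
    for lab, matrix in matrices.items():
        df, phi = _analyze_one(matrix, group_a, group_b)
        per_str[lab] = df
        dispersions[lab] = phi
        filter_logs[lab] = df.attrs.get("filter_log", pd.DataFrame())
    table = consensus_gcnvs(per_str, alpha=alpha, reference=reference)
    return DetectionOutput(
        table=table,
        dispersions=dispersions,
        filter_logs=filter_logs,
        per_stringency=per_str,
        alpha=alpha,
        group_a=group_a,
        group_b=group_b,
    )
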