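"""Label-permutation null for the number of detected copy-number variants.

The individuals are randomly reallocated into two balanced groups many
times; each reallocation reruns the same per-stringency analysis
(filter -> dispersion estimate -> exact test -> BH), and the number of
significant genes is recorded.  The empirical p-value of the observed count
uses the standard plus-one correction ``(#{null >= observed} + 1) /
(n_perm + 1)`` so it can never be exactly zero (a flag restores the raw
fraction).  The identity permutation, if drawn, is an ordinary null draw.

Both gene filters (median reads per 100 bp, zero-count individual) use all
individuals symmetrically and are therefore invariant under relabelling;
the filtered gene set is computed once per stringency and shared by every
permutation, which is identical to re-applying the filter each time.
Dispersion is genuinely label-dependent and is re-estimated per
permutation.  Inside permutations only the *count* of significant genes
matters, so exact p-values are computed for the genes a cheap screening
approximation cannot already place above ``alpha`` (see
:func:`paracnv.detect.exact_test_batch`); the observed count always uses
the exact test for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .counting import CountMatrix, filter_genes, normalize
from .detect import (
    _group_cond_loglik,
    _PHI_FLOOR,
    _PHI_MAX,
    equalize_library_sizes,
    exact_test_batch,
)

__all__ = ["PermutationNull", "run_permutation_test"]


@dataclass
class PermutationNull:
    """Null distribution of significant-gene counts over label reshuffles."""

    n_perm: int
    null_counts: np.ndarray
    observed_count: int
    empirical_p: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.null_counts) != self.n_perm:
            raise ValueError("null_counts length must equal n_perm")


def _empirical_p(null_counts: np.ndarray, observed: int, plus_one: bool) -> float:
    ge = int((null_counts >= observed).sum())
    if plus_one:
        return (ge + 1) / (len(null_counts) + 1)
    return ge / len(null_counts)


def _bh_significant(p: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of BH-significant p-values at level alpha."""
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    ps = np.sort(p)
    ok = ps <= alpha * np.arange(1, m + 1) / m
    if not ok.any():
        return np.zeros(m, dtype=bool)
    k = int(np.nonzero(ok)[0].max()) + 1
    return p <= alpha * k / m


def _fast_common_phi(
    pseudo: np.ndarray, masks: Sequence[np.ndarray], xatol: float
) -> float:
    def neg(phi: float) -> float:
        return -_group_cond_loglik(pseudo, masks, phi)

    res = optimize.minimize_scalar(
        neg, bounds=(1e-8, _PHI_MAX), method="bounded", options={"xatol": xatol}
    )
    phi = float(res.x)
    return 0.0 if phi < _PHI_FLOOR else phi


class _StringencyData:
    """Per-stringency precomputation shared by all permutations."""

    def __init__(self, matrix: CountMatrix):
        self.filtered, _ = filter_genes(matrix)
        if self.filtered.n_genes == 0:
            raise ValueError("no genes survive filtering")
        normalize(self.filtered)
        self.pseudo, _ = equalize_library_sizes(
            self.filtered.counts, self.filtered.totals
        )
        self.norm = self.filtered.normalized
        self.gene_ids = self.filtered.gene_ids

    def analyze(
        self,
        mask_a: np.ndarray,
        mask_b: np.ndarray,
        alpha: float,
        screen: bool,
        phi_xatol: float,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (BH-significant mask, direction sign) for one labelling."""
        phi = _fast_common_phi(self.pseudo, [mask_a, mask_b], phi_xatol)
        p = exact_test_batch(
            self.pseudo[:, mask_a].sum(axis=1),
            self.pseudo[:, mask_b].sum(axis=1),
            int(mask_a.sum()),
            int(mask_b.sum()),
            phi,
            screen_alpha=alpha if screen else None,
        )
        sig = _bh_significant(p, alpha)
        direction = np.sign(
            self.norm[:, mask_a].mean(axis=1) - self.norm[:, mask_b].mean(axis=1)
        )
        return sig, direction


def _consensus_count(
    sigs: list[np.ndarray],
    dirs: list[np.ndarray],
    shared_idx: list[np.ndarray],
) -> int:
    sig_all = None
    dir_ref = None
    agree = None
    for sig, direction, idx in zip(sigs, dirs, shared_idx):
        s = sig[idx]
        d = direction[idx]
        if sig_all is None:
            sig_all, dir_ref, agree = s.copy(), d, d != 0
        else:
            sig_all &= s
            agree &= (d == dir_ref) & (d != 0)
    return int((sig_all & agree).sum())


def run_permutation_test(
    matrices: Mapping[str, CountMatrix] | CountMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "per_stringency",
    alpha: float = 0.05,
    plus_one: bool = True,
    screen: bool = True,
    phi_xatol: float = 1e-4,
) -> dict[str, PermutationNull] | PermutationNull:
    """Permutation null of the GCNV count under balanced group reshuffles.

    Parameters
    ----------
    matrices
        Mapping from stringency label to its count matrix (a bare matrix is
        treated as one stringency).  All matrices must share the same
        samples in the same order, with two equal-sized groups.
    mode
        ``"per_stringency"`` returns one :class:`PermutationNull` per
        stringency (count = genes at FDR < alpha in that stringency);
        ``"consensus"`` returns a single null for the consensus count.
    screen
        Use the screened exact test inside permutations (identical counts,
        much faster); the observed count is always fully exact.
    """
    if isinstance(matrices, CountMatrix):
        matrices = {"default": matrices}
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("per_stringency", "consensus"):
        raise ValueError(f"unknown mode {mode!r}")

    labels = list(matrices)
    first = matrices[labels[0]]
    sample_ids = [s.sample_id for s in first.samples]
    for lab in labels[1:]:
        if [s.sample_id for s in matrices[lab].samples] != sample_ids:
            raise ValueError("stringency matrices must share identical samples")

    group_labels = list(dict.fromkeys(first.groups))
    if len(group_labels) != 2:
        raise ValueError(f"need exactly two groups, found {group_labels}")
    obs_mask_a = first.group_mask(group_labels[0])
    obs_mask_b = first.group_mask(group_labels[1])
    n = first.n_samples
    n_half = int(obs_mask_a.sum())
    if n_half != int(obs_mask_b.sum()):
        raise ValueError(
            f"groups must be balanced for the permutation test, got "
            f"{n_half} vs {n - n_half}"
        )

    data = {lab: _StringencyData(matrices[lab]) for lab in labels}

    shared_idx: list[np.ndarray] = []
    if mode == "consensus":
        universe = None
        for lab in labels:
            ids = data[lab].gene_ids
            universe = ids if universe is None else [
                g for g in universe if g in set(ids)
            ]
        if not universe:
            raise ValueError("empty shared gene universe across stringencies")
        for lab in labels:
            pos = {g: i for i, g in enumerate(data[lab].gene_ids)}
            shared_idx.append(np.array([pos[g] for g in universe]))

    def counts_for(mask_a: np.ndarray, mask_b: np.ndarray, scr: bool):
        sigs, dirs = [], []
        for lab in labels:
            sig, d = data[lab].analyze(mask_a, mask_b, alpha, scr, phi_xatol)
            sigs.append(sig)
            dirs.append(d)
        if mode == "consensus":
            return _consensus_count(sigs, dirs, shared_idx)
        return {lab: int(s.sum()) for lab, s in zip(labels, sigs)}

    observed = counts_for(obs_mask_a, obs_mask_b, scr=False)

    rng = np.random.default_rng(seed)
    if mode == "consensus":
        null = np.zeros(n_perm, dtype=np.int64)
    else:
        null = {lab: np.zeros(n_perm, dtype=np.int64) for lab in labels}
    for i in range(n_perm):
        order = rng.permutation(n)
        mask_a = np.zeros(n, dtype=bool)
        mask_a[order[:n_half]] = True
        mask_b = ~mask_a
        c = counts_for(mask_a, mask_b, scr=screen)
        if mode == "consensus":
            null[i] = c
        else:
            for lab in labels:
                null[lab][i] = c[lab]

    if mode == "consensus":
        return PermutationNull(
            n_perm=n_perm,
            null_counts=null,
            observed_count=int(observed),
            empirical_p=_empirical_p(null, int(observed), plus_one),
            label="consensus",
        )
    return {
        lab: PermutationNull(
            n_perm=n_perm,
            null_counts=null[lab],
            observed_count=observed[lab],
            empirical_p=_empirical_p(null[lab], observed[lab], plus_one),
            label=lab,
        )
        for lab in labels
    }
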