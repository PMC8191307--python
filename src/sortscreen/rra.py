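"""Gene-level robust rank aggregation (α-RRA) with a permutation null.

The positive-selection analysis for pooled screens: guides are scored by
their mean paired log2 fold-change across replicates (after total-count
normalization, with zero-count control guides removed), ranked descending,
and each gene's guides are summarized by the α-RRA statistic. For a gene
with k guides whose normalized ranks (rank/N) sorted ascending are
r(1) <= ... <= r(k),

    P_j = Pr[ j-th order statistic of k iid U(0,1) <= r(j) ]
        = I_{r(j)}(j, k - j + 1)                 (regularized incomplete Beta)
        = sum_{m >= j} C(k, m) r(j)^m (1 - r(j))^{k - m},

and rho = min over j with r(j) <= alpha of P_j (rho = 1 if no normalized
rank is within the top-alpha fraction). Significance comes from a
permutation null: for each gene size k, rho is recomputed on k normalized
ranks sampled at random from the pooled rank list without regard to gene
assignment, and p = (1 + #{null rho <= observed}) / (1 + n_perm), followed
by Benjamini-Hochberg correction across genes.

The guide-level score deliberately replaces the negative-binomial
mean-variance test used by model-based tools: after several rounds of
sorting the signal is presence/absence rather than a modest shift, and the
paired fold-change is the screen's own readout.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counttable import CountTable
from .library import NONTARGETING_GENE

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
DEFAULT_N_PERM = 1000


def normalize_total(counts: CountTable) -> CountTable:
    """Total-count normalization: scale each sample so its column total
    equals the mean of all column totals. Returns a real-valued table."""
    totals = {s: counts.column(s).sum() for s in counts.samples}
    for s, t in totals.items():
        if t <= 0:
            raise ValueError(f"sample {s!r} has zero total reads; cannot normalize")
    target = float(np.mean(list(totals.values())))
    frame = counts.counts.copy()
    for s in counts.samples:
        frame[s] = frame[s].astype(float) * (target / totals[s])
    return CountTable(counts=frame, stats=dict(counts.stats))


def sgrna_scores(
    counts: CountTable,
    pairs: Sequence[tuple[str, str]],
    pseudo: float = 0.5,
    drop_zero_control: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Score and rank guides for positive selection.

    Guides with a raw control (unsorted) count of zero in any replicate are
    removed first (zero in the control makes the ratio uninformative); the
    score is the mean over paired replicates of
    log2((sorted + pseudo)/(unsorted + pseudo)) on total-count-normalized
    values. Ranks are assigned descending by score (1 = most enriched),
    ties broken by sgRNA id; normrank = rank / N.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    keep = np.ones(len(counts.counts), dtype=bool)
    if drop_zero_control:
        for unsorted_name, _ in pairs:
            keep &= counts.column(unsorted_name).to_numpy() > 0
    if not keep.any():
        raise ValueError("no sgRNAs survive the zero-control filter")
    norm = normalize_total(counts) if normalize else counts
    sub = norm.counts.loc[keep]
    score = np.zeros(len(sub))
    for unsorted_name, sorted_name in pairs:
        u = sub[unsorted_name].to_numpy(dtype=float)
        s = sub[sorted_name].to_numpy(dtype=float)
        score += np.log2((s + pseudo) / (u + pseudo))
    score /= len(pairs)

    table = pd.DataFrame({"gene": sub["gene"], "score": score}, index=sub.index)
    order = np.lexsort((table.index.to_numpy(), -table["score"].to_numpy()))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    table["normrank"] = ranks / len(table)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d sgRNA(s) with zero control counts", n_dropped)
    table.attrs["n_dropped_zero_control"] = n_dropped
    return table


def rho_statistic(normranks: Sequence[float], alpha: float = DEFAULT_ALPHA) -> float:
    """α-RRA statistic for one gene's sorted ascending normalized ranks.

    Input must already be sorted (unsorted input is a contract violation,
    not silently fixed). Returns rho in (0, 1]; rho = 1 when no rank falls
    within the top-alpha fraction.
    """
    r = np.asarray(normranks, dtype=float)
    if r.ndim != 1 or r.size < 1:
        raise ValueError("normranks must be a non-empty 1-d sequence")
    if (np.diff(r) < 0).any():
        raise ValueError("normranks must be sorted ascending")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normranks must lie in (0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = r.size
    j = np.arange(1, k + 1)
    in_top = r <= alpha
    if not in_top.any():
        return 1.0
    pj = stats.beta.cdf(r[in_top], j[in_top], k - j[in_top] + 1)
    return float(pj.min())


def _rho_matrix(ranks: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise rho for a (n, k) matrix of normalized ranks (rows unsorted)."""
    r = np.sort(ranks, axis=1)
    n, k = r.shape
    j = np.arange(1, k + 1)
    pj = stats.beta.cdf(r, j[None, :], (k - j + 1)[None, :])
    pj = np.where(r <= alpha, pj, np.inf)
    rho = pj.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def permutation_pvalues(
    ranks: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    skip_nontargeting: bool = True,
) -> pd.DataFrame:
    """Gene-level results: rho, permutation p-value, BH FDR.

    The null distribution of rho for a gene with k guides is built by
    sampling, ``n_perm`` times, k of the observed normalized ranks uniformly
    at random (without replacement, ignoring gene assignment). Null
    distributions are computed once per distinct k and cached, so results
    do not depend on gene iteration order.

    p-values use the add-one rule, p = (1 + #{null rho <= observed}) /
    (1 + n_perm), with exact ties between observed and null rho broken
    uniformly at random (seeded). rho has a genuine atom at 1 — a gene with
    no guide in the top-alpha fraction, probability (1-alpha)^k under the
    null — and resolving that tie block conservatively would pile those
    genes' p-values onto 1 instead of spreading them over their exchangeable
    rank range; randomized tie rank restores the uniform null distribution
    while reducing to the plain add-one formula whenever there is no tie.
    p-values are never 0 and never exceed 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    tab = ranks
    if skip_nontargeting:
        tab = tab.loc[tab["gene"] != NONTARGETING_GENE]
    if tab.empty:
        raise ValueError("no targeting sgRNAs to aggregate")
    pooled = np.sort(tab["normrank"].to_numpy())  # row-order independent
    n_pool = pooled.size

    groups = tab.groupby("gene")
    genes = sorted(groups.groups)
    ks = {g: len(groups.get_group(g)) for g in genes}

    rng = np.random.default_rng(seed)
    null_by_k: dict[int, np.ndarray] = {}
    for k in sorted(set(ks.values())):
        if k > n_pool:
            raise ValueError(f"gene size {k} exceeds pooled rank count {n_pool}")
        draws = np.empty((n_perm, k))
        for p in range(n_perm):
            draws[p] = pooled[rng.choice(n_pool, size=k, replace=False)]
        null_by_k[k] = np.sort(_rho_matrix(draws, alpha))

    tie_u = rng.random(len(genes))  # randomized rank within exact tie blocks
    records = []
    for i, gene in enumerate(genes):
        sub = groups.get_group(gene)
        r = np.sort(sub["normrank"].to_numpy())
        rho = rho_statistic(r, alpha)
        null = null_by_k[ks[gene]]
        below = int(np.searchsorted(null, rho, side="left"))
        ties = int(np.searchsorted(null, rho, side="right")) - below
        p = (below + 1 + int(tie_u[i] * (ties + 1))) / (1 + n_perm)
        records.append((gene, ks[gene], rho, p, float(r[0])))
    result = pd.DataFrame(records, columns=["gene", "k", "rho", "p_perm", "best_rank"])
    result["fdr"] = multipletests(result["p_perm"].to_numpy(), method="fdr_bh")[1]
    result = result.sort_values(["p_perm", "rho", "gene"], kind="mergesort").reset_index(drop=True)
    result = result[["gene", "k", "rho", "p_perm", "fdr", "best_rank"]]
    result.attrs.update({"alpha": alpha, "n_perm": n_perm, "seed": seed})
    return result


def rra_analysis(
    counts: CountTable,
    pairs: Sequence[tuple[str, str]],
    pseudo: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full positive-selection analysis: normalize, score, aggregate.

    Returns (gene_results, sgrna_rank_table).
    """
    rank_table = sgrna_scores(counts, pairs, pseudo=pseudo)
    gene_results = permutation_pvalues(rank_table, alpha=alpha, n_perm=n_perm, seed=seed)
    return gene_results, rank_table
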