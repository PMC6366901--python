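"""Screen-level analysis: replicate reproducibility, mutant classification
and functional enrichment.

Replicates of a strain's growth-rate distribution are reproducible when,
after aligning means (allowed shift ≤ 0.05 h⁻¹), their Kolmogorov–Smirnov
distance stays ≤ 0.1; replicates form a graph and the largest clique of
mutually admissible replicates is kept.  Strains are then classified by
Mann–Whitney tests on per-replicate modes and mode-corrected slow
fractions (BH-FDR across strains), and gene groups are tested for
functional-class enrichment with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import hetstats
from .hetstats import ModeShiftCalibration

__all__ = [
    "ReplicateGraph",
    "ScreenRecord",
    "EnrichmentQuery",
    "ks_shifted_distance",
    "build_replicate_graph",
    "select_reproducible",
    "classify_screen",
    "hypergeom_enrichment",
    "enrichment_table",
    "bh_fdr",
    "CATEGORY_NAMES",
]

CATEGORY_NAMES = (
    "no-change",
    "mode-only",
    "slow-down-only",
    "slow-up-only",
    "both-down",
    "mode-down-slow-up",
    "other",
)


@dataclass
class ReplicateGraph:
    """Replicates as nodes; admissible pairs (K-S distance ≤ ``ks_max`` after
    mean alignment with shift ≤ ``mean_shift_max``) carry weighted edges."""

    graph: nx.Graph
    ks_max: float = 0.1
    mean_shift_max: float = 0.05


@dataclass
class ScreenRecord:
    """Classification outcome for one strain."""

    strain: str
    n_reproducible_replicates: int
    category: str | None = None
    mode_p: float | None = None
    mode_fdr: float | None = None
    slow_p: float | None = None
    slow_fdr: float | None = None
    mode_direction: int = 0  # sign of (mutant - WT) median mode
    slow_direction: int = 0
    penetrance_pct: float | None = None
    replicate_modes: list[float] = field(default_factory=list)
    replicate_slow_corrected: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric counts: ``N`` genes screened of which ``X`` belong to
    functional class f; a group of ``Ng`` genes contains ``Xg`` of them."""

    N: int
    X: int
    Ng: int
    Xg: int

    def __post_init__(self) -> None:
        if not (0 <= self.X <= self.N and 0 < self.Ng <= self.N):
            raise ValueError("require 0 <= X <= N and 0 < Ng <= N")
        if not 0 <= self.Xg <= min(self.X, self.Ng):
            raise ValueError("require 0 <= Xg <= min(X, Ng)")


def ks_shifted_distance(
    rep_a: np.ndarray,
    rep_b: np.ndarray,
    max_mean_shift: float = 0.05,
) -> float | None:
    """K-S distance between two replicate rate samples after mean alignment.

    ``rep_b`` is shifted by the difference in means; if that shift exceeds
    ``max_mean_shift`` (h⁻¹) the pair is inadmissible and None is returned,
    otherwise sup|ECDF_a − ECDF_b'|.
    """
    a = np.asarray(rep_a, dtype=float)
    b = np.asarray(rep_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty replicate sample")
    shift = a.mean() - b.mean()
    if abs(shift) > max_mean_shift:
        return None
    return float(stats.ks_2samp(a, b + shift, method="asymp").statistic)


def build_replicate_graph(
    replicates: list[np.ndarray],
    ks_max: float = 0.1,
    mean_shift_max: float = 0.05,
) -> ReplicateGraph:
    g = nx.Graph()
    g.add_nodes_from(range(len(replicates)))
    for i, j in itertools.combinations(range(len(replicates)), 2):
        d = ks_shifted_distance(replicates[i], replicates[j], mean_shift_max)
        if d is not None and d <= ks_max:
            g.add_edge(i, j, weight=d)
    return ReplicateGraph(graph=g, ks_max=ks_max, mean_shift_max=mean_shift_max)


def select_reproducible(graph: ReplicateGraph | nx.Graph) -> list[int]:
    """Largest clique of mutually admissible replicates (ties broken by the
    smallest total edge weight, then lexicographically); empty when no two
    replicates agree."""
    g = graph.graph if isinstance(graph, ReplicateGraph) else graph
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 replicates")
    best: tuple[int, float, tuple] | None = None
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        clique = sorted(clique)
        weight = sum(g[u][v]["weight"]
                     for u, v in itertools.combinations(clique, 2))
        key = (-len(clique), weight, tuple(clique))
        if best is None or key < best:
            best = key
    if best is None:
        return []
    return list(best[2])


def select_consistent_pool(graph: ReplicateGraph | nx.Graph,
                           min_degree_frac: float = 0.5) -> list[int]:
    """Majority-consistency selection for large reference pools.

    Keeps every replicate admissible with at least ``min_degree_frac`` of
    the other replicates.  Unlike the strict max-clique rule (appropriate
    for a strain's 3 replicates), this does not let one outlier day shrink
    a many-replicate wild-type pool below useful size.
    """
    g = graph.graph if isinstance(graph, ReplicateGraph) else graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 replicates")
    cut = min_degree_frac * (n - 1)
    return sorted(node for node in g.nodes if g.degree(node) >= cut)


# --------------------------------------------------------------------------
# Classification


def _replicate_summaries(replicates, calibration, wt_mode, min_n):
    modes, slows = [], []
    for rates in replicates:
        mode = hetstats.estimate_mode(rates, min_n=min_n)
        slow, _, _ = hetstats.slow_fast_fraction(rates, min_n=min_n)
        if calibration is not None:
            slow = calibration.correct(slow, mode_reduction=wt_mode - mode)
        modes.append(mode)
        slows.append(slow)
    return modes, slows


def _mwu(x, y) -> float:
    """Two-sided Mann–Whitney U p-value (exact for small tie-free samples,
    tie-corrected normal approximation otherwise)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0  # all values identical: no evidence either way
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def classify_screen(
    strains: dict[str, list[np.ndarray]],
    wt_replicates: list[np.ndarray],
    calibration: ModeShiftCalibration | None = None,
    fdr_q: float = 0.1,
    ks_max: float = 0.1,
    mean_shift_max: float = 0.05,
    min_n: int = hetstats.MIN_N,
    granularity: str = "replicate",
    compute_penetrance: bool = True,
) -> list[ScreenRecord]:
    """Classify every mutant strain against the wild type.

    Per strain, the reproducible replicate subset is selected via the K-S
    graph; strains keeping fewer than two replicates stay unclassified.
    Two Mann–Whitney U test families run across strains — replicate modes
    vs WT replicate modes, and mode-corrected slow fractions vs WT slow
    fractions — each BH-corrected separately at ``fdr_q``.  The category
    follows the two FDR calls and their directions.  ``granularity`` may
    be "replicate" (default; per-replicate summary values are the test
    samples) or "pooled" (single-cell rates pooled across replicates).

    The calibration defaults to one built from the WT replicates.
    """
    wt_graph = build_replicate_graph(wt_replicates, ks_max, mean_shift_max)
    wt_keep = select_consistent_pool(wt_graph)
    wt_reps = [wt_replicates[i] for i in wt_keep] if len(wt_keep) >= 2 else list(wt_replicates)
    if calibration is None:
        calibration = hetstats.mode_shift_calibration(wt_reps, min_n=min_n)
    wt_pool = np.concatenate(wt_reps)
    wt_mode = hetstats.estimate_mode(wt_pool, min_n=min_n)
    wt_modes, wt_slows = _replicate_summaries(wt_reps, calibration, wt_mode, min_n)

    records: list[ScreenRecord] = []
    tested: list[ScreenRecord] = []
    for strain, replicates in strains.items():
        graph = build_replicate_graph(replicates, ks_max, mean_shift_max)
        keep = select_reproducible(graph)
        rec = ScreenRecord(strain=strain, n_reproducible_replicates=len(keep))
        records.append(rec)
        if len(keep) < 2:
            continue
        reps = [replicates[i] for i in keep]
        modes, slows = _replicate_summaries(reps, calibration, wt_mode, min_n)
        rec.replicate_modes = modes
        rec.replicate_slow_corrected = slows
        if granularity == "pooled":
            rec.mode_p = _mwu(np.concatenate(reps), wt_pool)
            rec.slow_p = _mwu(slows, wt_slows)
        else:
            rec.mode_p = _mwu(modes, wt_modes)
            rec.slow_p = _mwu(slows, wt_slows)
        rec.mode_direction = int(np.sign(np.median(modes) - np.median(wt_modes)))
        rec.slow_direction = int(np.sign(np.median(slows) - np.median(wt_slows)))
        tested.append(rec)
        if compute_penetrance and np.median(modes) < np.median(wt_modes):
            _, mean_overlap, _ = hetstats.penetrance_overlap(reps, wt_reps,
                                                             min_n=min_n)
            rec.penetrance_pct = mean_overlap

    if tested:
        mode_rej, mode_adj = bh_fdr([r.mode_p for r in tested], q=fdr_q)
        slow_rej, slow_adj = bh_fdr([r.slow_p for r in tested], q=fdr_q)
        for rec, m_rej, m_adj, s_rej, s_adj in zip(tested, mode_rej, mode_adj,
                                                   slow_rej, slow_adj):
            rec.mode_fdr = float(m_adj)
            rec.slow_fdr = float(s_adj)
            rec.category = _category(bool(m_rej), rec.mode_direction,
                                     bool(s_rej), rec.slow_direction)
    return records


def _category(mode_sig: bool, mode_dir: int, slow_sig: bool, slow_dir: int) -> str:
    if not mode_sig and not slow_sig:
        return "no-change"
    if mode_sig and not slow_sig:
        return "mode-only"
    if not mode_sig and slow_sig:
        return "slow-up-only" if slow_dir > 0 else "slow-down-only"
    if mode_dir < 0 and slow_dir < 0:
        return "both-down"
    if mode_dir < 0 and slow_dir > 0:
        return "mode-down-slow-up"
    return "other"


# --------------------------------------------------------------------------
# Enrichment and FDR


def hypergeom_enrichment(q: EnrichmentQuery) -> float:
    """Upper-tail hypergeometric p-value: the probability that a random
    group of ``Ng`` of the ``N`` screened genes contains at least ``Xg``
    genes of the class (which has ``X`` members), computed in log space::

        p = sum_{i=Xg}^{min(Ng, X)} C(X, i) C(N-X, Ng-i) / C(N, Ng)
    """
    upper = min(q.Ng, q.X)
    if q.Xg == 0:
        return 1.0
    log_denom = (math.lgamma(q.N + 1) - math.lgamma(q.Ng + 1)
                 - math.lgamma(q.N - q.Ng + 1))
    logs = []
    for i in range(q.Xg, upper + 1):
        if q.Ng - i > q.N - q.X:
            continue
        lt = (math.lgamma(q.X + 1) - math.lgamma(i + 1) - math.lgamma(q.X - i + 1)
              + math.lgamma(q.N - q.X + 1) - math.lgamma(q.Ng - i + 1)
              - math.lgamma(q.N - q.X - (q.Ng - i) + 1))
        logs.append(lt - log_denom)
    if not logs:
        return 0.0
    m = max(logs)
    return float(min(1.0, math.exp(m) * sum(math.exp(v - m) for v in logs)))


def enrichment_table(
    group_genes: list[str],
    screened_genes: list[str],
    annotation: pd.DataFrame,
    fdr_q: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotation term in a gene group.

    ``annotation`` is a flat (gene, term) table.  Returns a frame (term,
    N, X, Ng, Xg, fold, p, fdr, significant) sorted by p.
    """
    group = set(group_genes)
    screened = set(screened_genes)
    if not group:
        raise ValueError("empty gene group")
    if not group <= screened:
        raise ValueError("group genes must be a subset of screened genes")
    ann = annotation[annotation["gene"].isin(screened)]
    N, Ng = len(screened), len(group)
    rows = []
    for term, genes in ann.groupby("term")["gene"]:
        members = set(genes)
        X = len(members)
        Xg = len(members & group)
        p = hypergeom_enrichment(EnrichmentQuery(N=N, X=X, Ng=Ng, Xg=Xg))
        expected = X * Ng / N
        rows.append({"term": term, "N": N, "X": X, "Ng": Ng, "Xg": Xg,
                     "fold": Xg / expected if expected > 0 else float("nan"),
                     "p": p})
    out = pd.DataFrame(rows).sort_values("p", ignore_index=True)
    rej, adj = bh_fdr(out["p"].tolist(), q=fdr_q)
    out["fdr"] = adj
    out["significant"] = rej
    return out


def bh_fdr(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted
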