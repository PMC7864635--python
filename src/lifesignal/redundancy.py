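"""Shared vs independent lifespan information between co-measured reporters.

When two reporters are measured in the same individuals (e.g. from
anatomically distinct tissues of a dual-reporter strain), their lifespan
information can be partitioned.  If the information is independent, the
R^2 of the joint regression on both reporters' (mean, slope) blocks equals
the sum of the two single-reporter R^2 values; if redundant, the joint R^2
collapses onto the better single reporter.  The *semipartial* (part) R^2
of reporter A given B — the increment in lifespan R^2 from adding A's
predictor block to a model already containing B's block — is the lifespan
variance uniquely attributable to A.

An informational hierarchy among reporters is a partial order: A >= B
means B adds no lifespan information beyond A (semipartial of B given A
indistinguishable from zero) while A does add information beyond B.  Since
an in-sample R^2 increment is never negative, "indistinguishable from
zero" is made operational with small-sample-adjusted (Ezekiel) increments,
whose bootstrap distribution is centered near zero under true redundancy:
an edge is asserted when the redundant direction's bootstrap interval
includes 0 and the other direction's interval excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import Dataset
from .regression import DegenerateOutcomeError, FeatureExtractor, TimeWindow, _r2
from .stats import BootstrapSpec, bootstrap_ci

__all__ = [
    "PairingError",
    "PairRedundancy",
    "HierarchyResult",
    "pair_features",
    "pair_redundancy",
    "semipartial_via_residualization",
    "infer_hierarchy",
    "coregulation_correlation",
]


class PairingError(ValueError):
    """The two reporters share no analyzable animals."""


def pair_features(
    dataset: Dataset,
    reporter_a: str,
    reporter_b: str,
    window: TimeWindow,
    statistic_a: str = "mean",
    statistic_b: str = "mean",
    min_obs: int = 3,
) -> pd.DataFrame:
    """Windowed features of both reporters on jointly eligible animals.

    Joint censoring: an animal enters only if it survives the window and
    has enough in-window observations for *both* reporters.  Columns:
    ``mean_a, slope_a, mean_b, slope_b, lifespan_h``.
    """
    fa = FeatureExtractor(dataset, reporter_a, statistic_a, min_obs).features(window)
    fb = FeatureExtractor(dataset, reporter_b, statistic_b, min_obs).features(window)
    joined = fa.join(fb, how="inner", lsuffix="_a", rsuffix="_b")
    if len(joined) == 0:
        raise PairingError(
            f"no animals carry both {reporter_a!r} and {reporter_b!r} in-window"
        )
    joined = joined.rename(columns={"lifespan_h_a": "lifespan_h"}).drop(
        columns=["lifespan_h_b", "n_obs_a", "n_obs_b"]
    )
    return joined


def _adjusted(r2: float, n: int, k: int) -> float:
    """Ezekiel small-sample adjustment, 1 - (1-R^2)(n-1)/(n-k-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class PairRedundancy:
    """Variance partition of lifespan between two reporters' feature blocks.

    ``additivity_gap = r2_a + r2_b - r2_pair``: near zero for independent
    information channels, near ``min(r2_a, r2_b)`` for full redundancy,
    negative under suppression.
    """

    reporter_a: str
    reporter_b: str
    n: int
    r2_a: float
    r2_b: float
    r2_pair: float
    sp_a_given_b: float
    sp_b_given_a: float
    additivity_gap: float
    window: TimeWindow | None = None
    sp_a_given_b_adj: float = float("nan")
    sp_b_given_a_adj: float = float("nan")
    ci_sp_a_given_b: tuple[float, float] | None = None
    ci_sp_b_given_a: tuple[float, float] | None = None


def _pair_r2s(y: np.ndarray, A: np.ndarray, B: np.ndarray) -> tuple[float, float, float]:
    r2_a, _ = _r2(y, A)
    r2_b, _ = _r2(y, B)
    r2_pair, _ = _r2(y, np.hstack([A, B]))
    return r2_a, r2_b, r2_pair


def pair_redundancy(
    dataset: Dataset,
    reporter_a: str,
    reporter_b: str,
    window: TimeWindow,
    statistic_a: str = "mean",
    statistic_b: str = "mean",
    min_obs: int = 3,
    bootstrap: BootstrapSpec | None = None,
) -> PairRedundancy:
    """Single, joint and semipartial R^2 for a reporter pair.

    Each reporter contributes a 2-predictor block (windowed mean and
    slope); semipartials are block R^2 increments.  The optional bootstrap
    resamples animals and recomputes the *adjusted* semipartial increments,
    yielding the intervals used for hierarchy edges.
    """
    feats = pair_features(
        dataset, reporter_a, reporter_b, window, statistic_a, statistic_b, min_obs
    )
    n = len(feats)
    if n < 6:
        raise DegenerateOutcomeError(f"need >= 6 jointly eligible animals, have {n}")
    y = feats["lifespan_h"].to_numpy(dtype=float)
    A = feats[["mean_a", "slope_a"]].to_numpy(dtype=float)
    B = feats[["mean_b", "slope_b"]].to_numpy(dtype=float)
    r2_a, r2_b, r2_pair = _pair_r2s(y, A, B)

    result = PairRedundancy(
        reporter_a=reporter_a,
        reporter_b=reporter_b,
        n=n,
        r2_a=r2_a,
        r2_b=r2_b,
        r2_pair=r2_pair,
        sp_a_given_b=r2_pair - r2_b,
        sp_b_given_a=r2_pair - r2_a,
        additivity_gap=r2_a + r2_b - r2_pair,
        window=window,
        sp_a_given_b_adj=_adjusted(r2_pair, n, 4) - _adjusted(r2_b, n, 2),
        sp_b_given_a_adj=_adjusted(r2_pair, n, 4) - _adjusted(r2_a, n, 2),
    )
    if bootstrap is not None:
        def sp_pair(idx: np.ndarray) -> tuple[float, float]:
            ra, rb, rp = _pair_r2s(y[idx], A[idx], B[idx])
            m = idx.size
            return (
                _adjusted(rp, m, 4) - _adjusted(rb, m, 2),
                _adjusted(rp, m, 4) - _adjusted(ra, m, 2),
            )

        res_a = bootstrap_ci(n, lambda idx: sp_pair(idx)[0], bootstrap)
        res_b = bootstrap_ci(n, lambda idx: sp_pair(idx)[1], bootstrap)
        result.ci_sp_a_given_b = res_a.ci
        result.ci_sp_b_given_a = res_b.ci
    return result


def semipartial_via_residualization(
    features: pd.DataFrame, block: str = "a"
) -> float:
    """Semipartial R^2 by the residualization route (cross-check).

    Residualizes the chosen reporter's block on the other block (with
    intercept) and regresses lifespan on the residualized block alone.
    Algebraically identical to the hierarchical R^2 increment; computed
    through a different pipeline so the OLS identity can be asserted.
    """
    other = "b" if block == "a" else "a"
    y = features["lifespan_h"].to_numpy(dtype=float)
    A = features[[f"mean_{block}", f"slope_{block}"]].to_numpy(dtype=float)
    B = features[[f"mean_{other}", f"slope_{other}"]].to_numpy(dtype=float)
    B1 = np.column_stack([np.ones(len(B)), B])
    A_resid = A - B1 @ np.linalg.lstsq(B1, A, rcond=None)[0]
    yc = y - y.mean()
    coef, _, _, _ = np.linalg.lstsq(A_resid, yc, rcond=None)
    fitted = A_resid @ coef
    return float(fitted @ fitted) / float(yc @ yc)


# -- hierarchy -----------------------------------------------------------


@dataclass
class HierarchyResult:
    """Pairwise redundancy matrix and the induced informational order.

    ``edges`` lists (upper, lower) pairs, meaning the upper reporter
    carries strictly more lifespan information.  ``consistent`` is False
    when the pairwise evidence is cyclic, which is reported rather than
    silently resolved.
    """

    reporters: list[str]
    pairs: list[PairRedundancy]
    edges: list[tuple[str, str]]
    consistent: bool
    threshold: float

    def holds(self, upper: str, lower: str) -> bool:
        """Whether ``upper >= lower`` in the inferred order (transitively).

        The asserted edges generate the partial order; being an order it is
        closed under transitivity.  Returns False on inconsistent evidence.
        """
        if not self.consistent:
            return False
        g = nx.DiGraph(self.edges)
        g.add_nodes_from(self.reporters)
        return nx.has_path(g, upper, lower) and upper != lower

    def order_description(self) -> str:
        if not self.consistent:
            return "inconsistent (cyclic pairwise evidence)"
        if not self.edges:
            return "no strict order established"
        g = nx.DiGraph(self.edges)
        chains = []
        for comp in nx.weakly_connected_components(g):
            sub = g.subgraph(comp)
            chains.append(" >= ".join(nx.topological_sort(sub)))
        return "; ".join(sorted(chains))

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "reporter_a": p.reporter_a,
                    "reporter_b": p.reporter_b,
                    "n": p.n,
                    "r2_a": p.r2_a,
                    "r2_b": p.r2_b,
                    "r2_pair": p.r2_pair,
                    "sp_a_given_b": p.sp_a_given_b,
                    "sp_b_given_a": p.sp_b_given_a,
                    "additivity_gap": p.additivity_gap,
                }
            )
        return pd.DataFrame(rows)


def infer_hierarchy(
    dataset: Dataset,
    reporters: list[str],
    window: TimeWindow,
    statistics: dict[str, str] | None = None,
    bootstrap: BootstrapSpec | None = None,
    threshold: float = 0.0,
    min_obs: int = 3,
) -> HierarchyResult:
    """Infer the informational partial order among >= 2 reporters.

    For each unordered pair the adjusted semipartial increments and their
    bootstrap intervals are computed over a common window; the edge
    A >= B is asserted when B's increment given A has an interval reaching
    ``threshold`` or below (default 0: redundancy not distinguishable from
    none) while A's increment given B has an interval lying entirely above
    it.  Cyclic edge evidence is flagged, not resolved.
    """
    if len(reporters) < 2:
        raise ValueError("need at least two reporters")
    if bootstrap is None:
        bootstrap = BootstrapSpec()
    statistics = statistics or {}
    pairs = []
    edges = []
    for i, a in enumerate(reporters):
        for b in reporters[i + 1 :]:
            pr = pair_redundancy(
                dataset,
                a,
                b,
                window,
                statistic_a=statistics.get(a, "mean"),
                statistic_b=statistics.get(b, "mean"),
                min_obs=min_obs,
                bootstrap=bootstrap,
            )
            pairs.append(pr)
            a_low, _ = pr.ci_sp_a_given_b
            b_low, _ = pr.ci_sp_b_given_a
            a_adds = a_low > threshold  # interval excludes the null band
            b_adds = b_low > threshold
            if a_adds and not b_adds:
                edges.append((a, b))
            elif b_adds and not a_adds:
                edges.append((b, a))
    g = nx.DiGraph()
    g.add_nodes_from(reporters)
    g.add_edges_from(edges)
    consistent = nx.is_directed_acyclic_graph(g)
    return HierarchyResult(list(reporters), pairs, edges, consistent, threshold)


# -- co-regulation -------------------------------------------------------


def coregulation_correlation(
    dataset: Dataset,
    reporter_a: str,
    reporter_b: str,
    window: TimeWindow,
    statistic_a: str = "mean",
    statistic_b: str = "mean",
    min_obs: int = 3,
) -> dict[str, float]:
    """Cross-reporter Pearson correlation of windowed features.

    Correlated mean (and slope) features across animals indicate
    co-regulation of the two reporters — the mechanistic substrate of
    informational redundancy.
    """
    feats = pair_features(
        dataset, reporter_a, reporter_b, window, statistic_a, statistic_b, min_obs
    )
    if len(feats) < 3:
        raise DegenerateOutcomeError("need >= 3 jointly eligible animals")
    return {
        "n": len(feats),
        "mean_correlation": float(np.corrcoef(feats["mean_a"], feats["mean_b"])[0, 1]),
        "slope_correlation": float(np.corrcoef(feats["slope_a"], feats["slope_b"])[0, 1]),
    }
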