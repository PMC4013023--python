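"""Boundary significance testing on dendrogram nodes and partition extraction.

At each node the trinary significance matrix restricted to the node's leaves
is split into zones: within group A, within group B, and the between-group
intersection A*B.  Weak segregation (DW, GW) asks whether significantly high
similarities concentrate inside A and B but not across; strong segregation
(DS, GS) asks whether significantly low similarities concentrate across.
Significance of each pattern comes from a G-test of independence with Yates'
correction on the 2×2 table pooling the two within zones against the between
zone.  Biotic regions (Q-mode) and chorotypes (R-mode) are the subtrees left
when top-down recursion stops at the first non-significant boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .clustering import Dendrogram, MergeNode
from .similarity import TrinarySignificanceMatrix

__all__ = [
    "ZoneCounts",
    "zone_counts",
    "dw_ds",
    "g_test_yates",
    "g_test_zones_williams",
    "NodeBoundaryStats",
    "node_boundary",
    "extract_partition",
    "boundary_report",
    "Partition",
    "to_roman",
]

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def to_roman(k: int) -> str:
    numerals = (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
        (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    )
    if k < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in numerals:
        while k >= value:
            out.append(sym)
            k -= value
    return "".join(out)


@dataclass(frozen=True)
class ZoneCounts:
    """Pair totals and significant-similarity counts per zone."""

    n_aa: int
    n_bb: int
    n_ab: int
    p_aa: int  #: +1 pairs within A
    p_bb: int
    p_ab: int
    q_aa: int  #: −1 pairs within A
    q_bb: int
    q_ab: int


def zone_counts(group_a, group_b, sig: TrinarySignificanceMatrix) -> ZoneCounts:
    """Count significant similarities in zones A, B and A*B for a split."""
    a = sorted(group_a)
    b = sorted(group_b)
    missing = (set(a) | set(b)) - set(sig.labels)
    if missing:
        raise KeyError(f"labels absent from significance matrix: {sorted(missing)}")
    idx = {lab: i for i, lab in enumerate(sig.labels)}
    ia = [idx[l] for l in a]
    ib = [idx[l] for l in b]
    V = sig.values

    def within(ids):
        sub = V[np.ix_(ids, ids)]
        tri = sub[np.triu_indices(len(ids), k=1)]
        return int((tri == 1).sum()), int((tri == -1).sum())

    p_aa, q_aa = within(ia)
    p_bb, q_bb = within(ib)
    cross = V[np.ix_(ia, ib)]
    return ZoneCounts(
        n_aa=len(a) * (len(a) - 1) // 2,
        n_bb=len(b) * (len(b) - 1) // 2,
        n_ab=len(a) * len(b),
        p_aa=p_aa, p_bb=p_bb, p_ab=int((cross == 1).sum()),
        q_aa=q_aa, q_bb=q_bb, q_ab=int((cross == -1).sum()),
    )


def dw_ds(counts: ZoneCounts) -> tuple[float, float, float, float]:
    """Boundary efficiency statistics (DW_AA, DW_BB, DW, DS).

    DW_AA = p(A*A)/n(A*A) − p(A*B)/n(A*B) (zero when the group is a
    singleton), DW_BB analogously, DW is their unweighted mean.  DS =
    q(A*B)/n(A*B) minus the pooled within-zone −1 rate.
    """
    p_ab_rate = counts.p_ab / counts.n_ab
    dw_aa = (counts.p_aa / counts.n_aa - p_ab_rate) if counts.n_aa else 0.0
    dw_bb = (counts.p_bb / counts.n_bb - p_ab_rate) if counts.n_bb else 0.0
    dw = (dw_aa + dw_bb) / 2.0
    n_within = counts.n_aa + counts.n_bb
    within_rate = (counts.q_aa + counts.q_bb) / n_within if n_within else 0.0
    ds = counts.q_ab / counts.n_ab - within_rate
    return dw_aa, dw_bb, dw, ds


def g_test_yates(k11: int, k12: int, k21: int, k22: int) -> tuple[float, float]:
    """G-test of independence on a 2×2 table with Yates' correction.

    Each observed count is moved 0.5 toward its expectation (never across
    it); G = 2 Σ O' ln(O'/E) with the 0·ln 0 convention, compared to χ² with
    one degree of freedom.  A zero row or column margin carries no
    information and returns (0, 1).
    """
    obs = np.array([[k11, k12], [k21, k22]], dtype=float)
    if (obs < 0).any():
        raise ValueError("contingency counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ValueError("contingency table is empty")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    adjusted = obs + np.clip(expected - obs, -0.5, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(adjusted > 0, adjusted * np.log(adjusted / expected), 0.0)
    G = max(2.0 * terms.sum(), 0.0)
    return float(G), float(chi2.sf(G, df=1))


def g_test_zones_williams(observed: np.ndarray) -> tuple[float, float]:
    """Zone-resolved 2×k G-test with Williams' correction (alternative to
    pooling; k−1 degrees of freedom)."""
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any() or total == 0:
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    G = 2.0 * terms.sum()
    q = 1.0 + ((total / rows).sum() - 1.0) * ((total / cols).sum() - 1.0) / (
        6.0 * total * (obs.shape[0] - 1) * (obs.shape[1] - 1)
    )
    G = max(G / q, 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(G), float(chi2.sf(G, df=df))


def _stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    stars = sum(p < t for t in thresholds)
    return "*" * stars if stars else "n.s."


@dataclass(frozen=True)
class NodeBoundaryStats:
    """Segregation statistics for one dendrogram node."""

    node_id: int
    group_a: frozenset[str]
    group_b: frozenset[str]
    height: float
    counts: ZoneCounts
    dw_aa: float
    dw_bb: float
    dw: float
    ds: float
    gw: float
    p_gw: float
    gs: float
    p_gs: float
    boundary_class: str = field(init=False)
    gw_stars: str = field(init=False)
    gs_stars: str = field(init=False)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        weak = self.p_gw < self.alpha and self.dw > 0
        strong = self.p_gs < self.alpha and self.ds > 0
        cls = {
            (False, False): "none", (True, False): "weak",
            (False, True): "strong", (True, True): "both",
        }[(weak, strong)]
        object.__setattr__(self, "boundary_class", cls)
        object.__setattr__(self, "gw_stars", _stars(self.p_gw))
        object.__setattr__(self, "gs_stars", _stars(self.p_gs))


def node_boundary(node: MergeNode, sig: TrinarySignificanceMatrix,
                  alpha: float = 0.05, contingency: str = "pooled") -> NodeBoundaryStats:
    """Test one node's split for weak and strong segregation.

    GW comes from the 2×2 table {within pairs (A*A ∪ B*B) vs between (A*B)}
    × {+1 vs not +1} with Yates' correction; GS likewise with −1 counts.
    ``contingency="zones"`` keeps the three zones separate (Williams'
    correction, 2 df) instead of pooling.
    """
    if len(node.members) < 2:
        raise ValueError("boundary test needs a node with at least two leaves")
    c = zone_counts(node.left_members, node.right_members, sig)
    dw_aa, dw_bb, dw, ds = dw_ds(c)
    n_within = c.n_aa + c.n_bb
    p_within = c.p_aa + c.p_bb
    q_within = c.q_aa + c.q_bb
    if contingency == "pooled":
        gw, p_gw = g_test_yates(p_within, n_within - p_within, c.p_ab, c.n_ab - c.p_ab)
        gs, p_gs = g_test_yates(q_within, n_within - q_within, c.q_ab, c.n_ab - c.q_ab)
    elif contingency == "zones":
        gw, p_gw = g_test_zones_williams(np.array(
            [[c.p_aa, c.p_bb, c.p_ab],
             [c.n_aa - c.p_aa, c.n_bb - c.p_bb, c.n_ab - c.p_ab]]))
        gs, p_gs = g_test_zones_williams(np.array(
            [[c.q_aa, c.q_bb, c.q_ab],
             [c.n_aa - c.q_aa, c.n_bb - c.q_bb, c.n_ab - c.q_ab]]))
    else:
        raise ValueError(f"unknown contingency variant: {contingency!r}")
    return NodeBoundaryStats(
        node_id=node.id, group_a=node.left_members, group_b=node.right_members,
        height=node.height, counts=c, dw_aa=dw_aa, dw_bb=dw_bb, dw=dw, ds=ds,
        gw=gw, p_gw=p_gw, gs=gs, p_gs=p_gs, alpha=alpha,
    )


@dataclass(frozen=True)
class Partition:
    """Disjoint cover of the dendrogram leaves, named with roman numerals in
    dendrogram order (groups splitting off nearest the root first)."""

    groups: tuple[frozenset[str], ...]
    names: tuple[str, ...]
    mode: str = "Q"

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(frozenset(g) for g in self.groups))
        object.__setattr__(self, "names", tuple(self.names))
        all_members = [m for g in self.groups for m in g]
        if len(all_members) != len(set(all_members)):
            raise ValueError("partition groups must be disjoint")

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(m for g in self.groups for m in g)

    def group_of(self, member: str) -> str:
        for name, group in zip(self.names, self.groups):
            if member in group:
                return name
        raise KeyError(member)

    def membership(self) -> dict[str, str]:
        return {m: name for name, g in zip(self.names, self.groups) for m in g}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": member, "group": name}
            for name, group in zip(self.names, self.groups)
            for member in sorted(group)
        ]
        return pd.DataFrame(rows)


def _recurse(tree: Dendrogram, sig: TrinarySignificanceMatrix, alpha: float,
             contingency: str) -> tuple[list[NodeBoundaryStats], list[frozenset[str]]]:
    """Top-down recursion from the root.

    Descent halts at the first non-significant node; deeper nodes are not
    tested.  Children are visited left (earlier-formed) first, which yields
    groups in dendrogram order.  Returns the tested-node statistics in visit
    order and the resulting groups.
    """
    by_members = {n.members: n for n in tree.nodes}
    tested: list[NodeBoundaryStats] = []
    groups: list[frozenset[str]] = []

    def visit(members: frozenset[str]) -> None:
        node = by_members.get(members)
        if node is None:  # a single leaf reached by splitting
            groups.append(members)
            return
        stats = node_boundary(node, sig, alpha=alpha, contingency=contingency)
        tested.append(stats)
        if stats.boundary_class != "none":
            visit(node.left_members)
            visit(node.right_members)
        else:
            groups.append(members)

    visit(frozenset(tree.leaves))
    return tested, groups


def extract_partition(tree: Dendrogram, sig: TrinarySignificanceMatrix,
                      alpha: float = 0.05, contingency: str = "pooled") -> Partition:
    """Cut the dendrogram into significant groups.

    From the root downwards, each node showing a weak or strong boundary is
    split and its children recursed into; a subtree whose top node shows no
    boundary becomes one group.  Singletons isolated by a split are groups
    of size one.
    """
    _, groups = _recurse(tree, sig, alpha, contingency)
    names = tuple(to_roman(i + 1) for i in range(len(groups)))
    return Partition(groups=tuple(groups), names=names, mode=sig.mode)


def boundary_report(tree: Dendrogram, sig: TrinarySignificanceMatrix,
                    alpha: float = 0.05, contingency: str = "pooled",
                    only_significant: bool = False) -> pd.DataFrame:
    """Tabulate segregation statistics for the nodes the recursion tests.

    One row per tested node with the cophenetic distance, DW components, GW,
    DS and GS with significance stars — column-compatible with published
    segregation tables.
    """
    tested, _ = _recurse(tree, sig, alpha, contingency)
    rows = []
    for stats in tested:
        rows.append({
            "group_a": ";".join(sorted(stats.group_a)),
            "group_b": ";".join(sorted(stats.group_b)),
            "distance": stats.height,
            "dw_aa": stats.dw_aa,
            "dw_bb": stats.dw_bb,
            "dw": stats.dw,
            "gw": stats.gw,
            "p_gw": stats.p_gw,
            "gw_stars": stats.gw_stars,
            "ds": stats.ds,
            "gs": stats.gs,
            "p_gs": stats.p_gs,
            "gs_stars": stats.gs_stars,
            "boundary_class": stats.boundary_class,
        })
    report = pd.DataFrame(rows)
    if only_significant and len(report):
        report = report[report["boundary_class"] != "none"].reset_index(drop=True)
    return report
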