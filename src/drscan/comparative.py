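"""Comparative longevity statistics with phylogenetic correction.

The core chain is: regress (log-) lifespan and the repeat statistic on
(log-) body mass at the species level, transform the residuals into
Felsenstein's phylogenetically independent contrasts (PICs) on a user
supplied tree, and correlate the contrasts through the origin. Around it
sit the supporting tests used throughout the analysis: subpopulation
comparisons at lifespan percentiles (t / Mann-Whitney / Kolmogorov-
Smirnov), Z-tests of a native DR count against a randomized ensemble,
pairwise Mann-Whitney matrices across taxonomic groups, and the upper
"constraint line" least-squares fit through chosen support species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .dr_scan import DRSpectrum

logger = logging.getLogger(__name__)


@dataclass
class SpeciesRecord:
    """Trait and sequence summary for one species."""

    species: str
    taxon_order: str
    lifespan: float  # years, maximum across sources
    body_mass: float  # grams, mean across sources
    dr_spectrum: DRSpectrum | None = None
    nc: float | None = None
    gc3: float | None = None
    gc_content: float | None = None
    gc_skew: float | None = None
    at_skew: float | None = None
    tms: float | None = None

    def __post_init__(self) -> None:
        if self.lifespan <= 0:
            raise ValueError(f"{self.species}: lifespan must be > 0")
        if self.body_mass <= 0:
            raise ValueError(f"{self.species}: body mass must be > 0")


# ---------------------------------------------------------------------------
# Residuals
# ---------------------------------------------------------------------------

def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on covariates ``X`` plus an intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Standardized contrasts for one trait, in fixed postorder node order."""

    values: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.values)


def load_tree(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string)."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def prepare_tree(tree: dendropy.Tree, min_branch_fraction: float = 1e-8) -> dendropy.Tree:
    """Resolve polytomies and replace zero/missing branch lengths.

    Polytomies are resolved arbitrarily with zero-length branches, which are
    then (like any other zero or missing internal branch) replaced by
    ``min_branch_fraction`` times the tree height, so that contrast
    variances stay strictly positive.
    """
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()
    height = max(leaf.distance_from_root() or 0.0 for leaf in tree.leaf_node_iter())
    eps = min_branch_fraction * (height if height > 0 else 1.0)
    n_fixed = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps
            n_fixed += 1
    if n_fixed:
        logger.info("adjusted %d zero/missing branch lengths to %.3g", n_fixed, eps)
    return tree


def independent_contrasts(tree: dendropy.Tree, trait: dict[str, float],
                          resolve: bool = True) -> ContrastSet:
    """Felsenstein's standardized contrasts of a leaf trait on a rooted tree.

    At each internal node with children (x1, v1) and (x2, v2) — trait
    estimate and branch length plus accumulated correction — the
    standardized contrast is (x1 - x2)/sqrt(v1 + v2); the node's ancestral
    estimate is the precision-weighted average and its parent branch is
    lengthened by v1*v2/(v1 + v2).
    """
    if resolve:
        tree = prepare_tree(tree)
    contrasts: list[float] = []
    labels: list[str] = []
    values: dict[int, float] = {}
    extra: dict[int, float] = {}

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            if name not in trait:
                raise ValueError(f"leaf {name!r} has no trait value")
            values[id(node)] = float(trait[name])
            extra[id(node)] = 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be binary (use prepare_tree to resolve polytomies)")
        (c1, c2) = children
        v1 = (c1.edge.length or 0.0) + extra[id(c1)]
        v2 = (c2.edge.length or 0.0) + extra[id(c2)]
        pooled = v1 + v2
        if pooled <= 0:
            raise ValueError("zero pooled branch variance at an internal node")
        contrasts.append((values[id(c1)] - values[id(c2)]) / math.sqrt(pooled))
        labels.append(node.label or f"node{len(contrasts)}")
        values[id(node)] = (values[id(c1)] / v1 + values[id(c2)] / v2) / (1 / v1 + 1 / v2)
        extra[id(node)] = v1 * v2 / pooled
    return ContrastSet(values=np.array(contrasts), node_labels=tuple(labels))


def contrast_correlation(cx: ContrastSet, cy: ContrastSet,
                         through_origin: bool = True) -> tuple[float, float]:
    """Correlation of two contrast sets (through the origin by default).

    rho = sum(x*y) / sqrt(sum(x^2) * sum(y^2)), with a t-test on k-1
    degrees of freedom for k contrasts (k-2 for the non-origin variant,
    provided for sensitivity analysis).
    """
    x = np.asarray(cx.values, dtype=float)
    y = np.asarray(cy.values, dtype=float)
    if len(x) != len(y):
        raise ValueError("contrast sets differ in length (different trees?)")
    k = len(x)
    if k < 3:
        raise ValueError("need at least 3 contrasts")
    if through_origin:
        denom = math.sqrt(float(np.sum(x * x)) * float(np.sum(y * y)))
        if denom == 0:
            raise ValueError("zero variance in contrasts")
        rho = float(np.sum(x * y)) / denom
        df = k - 1
    else:
        rho = float(np.corrcoef(x, y)[0, 1])
        df = k - 2
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def pic_partial_correlation(
    tree: dendropy.Tree,
    y: dict[str, float],
    x: dict[str, float],
    controls: list[dict[str, float]] | None = None,
    order: str = "contrast",
    resolve: bool = True,
) -> tuple[float, float, int]:
    """Phylogenetically corrected (partial) correlation of two leaf traits.

    With ``order="contrast"`` (default) the raw traits and every control are
    first transformed into independent contrasts; the x- and y-contrasts
    are then residualized on the control contrasts by through-origin least
    squares and correlated through the origin, with k - c - 1 degrees of
    freedom for k contrasts and c controls. This ordering keeps the nominal
    type-I error of the whole chain at its level under Brownian nulls.

    ``order="leaf"`` residualizes at the leaf level (ordinary OLS with an
    intercept) before taking contrasts — the ordering sometimes used in the
    comparative literature. It is provided for sensitivity analysis; leaf
    level residuals are no longer tree-independent, which makes this
    variant anticonservative (inflated false-positive rate) on large trees.

    Returns ``(rho, p, k)``.
    """
    controls = controls or []
    if resolve:
        tree = prepare_tree(tree)
    species = sorted(y)
    if order == "contrast":
        cy = independent_contrasts(tree, y, resolve=False).values
        cx = independent_contrasts(tree, x, resolve=False).values
        k = len(cy)
        if controls:
            cz = np.column_stack([
                independent_contrasts(tree, c, resolve=False).values for c in controls
            ])
            # through-origin projection onto the control contrasts
            beta_y, *_ = np.linalg.lstsq(cz, cy, rcond=None)
            beta_x, *_ = np.linalg.lstsq(cz, cx, rcond=None)
            cy = cy - cz @ beta_y
            cx = cx - cz @ beta_x
        df = k - len(controls) - 1
    elif order == "leaf":
        yv = np.array([y[s] for s in species])
        xv = np.array([x[s] for s in species])
        if controls:
            Z = np.column_stack([[c[s] for s in species] for c in controls])
            yv = residualize(yv, Z)
            xv = residualize(xv, Z)
        cy = independent_contrasts(tree, dict(zip(species, yv)), resolve=False).values
        cx = independent_contrasts(tree, dict(zip(species, xv)), resolve=False).values
        k = len(cy)
        df = k - 1
    else:
        raise ValueError(f"unknown ordering {order!r}")
    if df < 1:
        raise ValueError("not enough contrasts for the requested controls")
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    if denom == 0:
        raise ValueError("zero variance in contrasts")
    rho = max(-1.0, min(1.0, float(cx @ cy) / denom))
    if abs(rho) >= 1.0:
        return rho, 0.0, k
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), df)), k


# ---------------------------------------------------------------------------
# Subpopulation comparisons
# ---------------------------------------------------------------------------

@dataclass
class SubpopulationReport:
    percentile: float
    threshold: float
    n_short: int
    n_long: int
    t_stat: float
    t_p: float
    mwu_stat: float
    mwu_p: float
    ks_stat: float
    ks_p: float
    alternative: str


def split_at_percentile(lifespans: np.ndarray, percentile: float) -> np.ndarray:
    """Boolean mask of the short-lived group (ties at the threshold go short)."""
    threshold = float(np.percentile(lifespans, percentile))
    return lifespans <= threshold


def subpopulation_tests(lifespans: np.ndarray, values: np.ndarray,
                        percentile: float = 50.0,
                        alternative: str = "two-sided") -> SubpopulationReport:
    """Compare a statistic between short- and long-lived subpopulations.

    Short-lived species are those with lifespan at or below the given
    percentile of the lifespan distribution. ``alternative`` follows scipy
    semantics with the short-lived group first (e.g. ``"greater"`` tests
    whether short-lived species have larger values). Means are compared by
    a two-sample t-test, medians by Mann-Whitney U (exact when both groups
    are small and tie-free), and full distributions by the two-sample
    Kolmogorov-Smirnov test.
    """
    lifespans = np.asarray(lifespans, dtype=float)
    values = np.asarray(values, dtype=float)
    threshold = float(np.percentile(lifespans, percentile))
    short_mask = lifespans <= threshold
    short, long_ = values[short_mask], values[~short_mask]
    if len(short) == 0 or len(long_) == 0:
        raise ValueError(f"empty subpopulation at percentile {percentile}")
    t_stat, t_p = stats.ttest_ind(short, long_, alternative=alternative)
    has_ties = len(np.unique(np.concatenate([short, long_]))) < len(short) + len(long_)
    method = "exact" if (len(short) <= 20 and len(long_) <= 20 and not has_ties) else "asymptotic"
    mwu_stat, mwu_p = stats.mannwhitneyu(short, long_, alternative=alternative, method=method)
    ks_alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    ks_stat, ks_p = stats.ks_2samp(short, long_, alternative=ks_alternative)
    return SubpopulationReport(
        percentile=percentile, threshold=threshold,
        n_short=len(short), n_long=len(long_),
        t_stat=float(t_stat), t_p=float(t_p),
        mwu_stat=float(mwu_stat), mwu_p=float(mwu_p),
        ks_stat=float(ks_stat), ks_p=float(ks_p),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Ensemble Z-test, constraint line, pairwise group tests
# ---------------------------------------------------------------------------

def ensemble_z_test(native_count: float, ensemble, sided: str = "two") -> tuple[float, float]:
    """Z-test of a native DR count against a null ensemble's mean and sd.

    ``ensemble`` is a :class:`~drscan.randomize.NullEnsemble` or a
    ``(mean, sd)`` pair. ``sided`` is "two", "greater" (native above null)
    or "less".
    """
    if hasattr(ensemble, "mean") and hasattr(ensemble, "sd"):
        mean, sd = float(ensemble.mean), float(ensemble.sd)
    else:
        mean, sd = map(float, ensemble)
    if sd <= 0:
        raise ValueError("ensemble standard deviation must be > 0")
    z = (float(native_count) - mean) / sd
    if sided == "two":
        p = 2.0 * stats.norm.sf(abs(z))
    elif sided == "greater":
        p = float(stats.norm.sf(z))
    elif sided == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(z), float(p)


@dataclass
class ConstraintLine:
    slope: float
    intercept: float
    support: tuple[str, ...]
    above: tuple[str, ...]  # points strictly above the fitted line


def constraint_line(ids: list[str], x: np.ndarray, y: np.ndarray,
                    support: list[str], exclude: list[str] | None = None,
                    tol: float = 1e-9) -> ConstraintLine:
    """Least-squares line through chosen support points only.

    Used to draw an upper "constraint" boundary (e.g. long-DR count vs
    lifespan) from a handful of boundary species, optionally excluding
    outliers; every point lying above the fitted line is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exclude = set(exclude or [])
    sup = [s for s in support if s not in exclude]
    idx = [ids.index(s) for s in sup]
    if len(idx) < 2:
        raise ValueError("need at least 2 support points after exclusions")
    slope, intercept = np.polyfit(x[idx], y[idx], 1)
    above = tuple(ids[i] for i in range(len(ids))
                  if y[i] > slope * x[i] + intercept + tol)
    return ConstraintLine(slope=float(slope), intercept=float(intercept),
                          support=tuple(sup), above=above)


def group_pairwise_tests(groups: dict[str, np.ndarray],
                         alternative: str = "two-sided") -> pd.DataFrame:
    """Pairwise Mann-Whitney U p-value matrix across taxonomic groups.

    Raw p-values (no multiplicity correction); groups with fewer than 2
    members are flagged and their pairs left as NaN.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, gi in enumerate(names):
        for j, gj in enumerate(names):
            if i == j:
                continue
            a, b = np.asarray(groups[gi], float), np.asarray(groups[gj], float)
            if len(a) < 2 or len(b) < 2:
                logger.warning("degenerate group (%s or %s): pair skipped", gi, gj)
                continue
            _, p = stats.mannwhitneyu(a, b, alternative=alternative)
            mat.loc[gi, gj] = float(p)
    return mat


def pairwise_tests_by_order(records: list[SpeciesRecord], dr_min_len: int,
                            alternative: str = "two-sided") -> pd.DataFrame:
    """Pairwise MWU matrix of total DR counts (>= dr_min_len) by taxon order."""
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.dr_spectrum is None:
            raise ValueError(f"{r.species}: no DR spectrum")
        groups.setdefault(r.taxon_order, []).append(r.dr_spectrum.total(dr_min_len))
    return group_pairwise_tests({k: np.array(v) for k, v in groups.items()},
                                alternative=alternative)
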