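"""Phylodynamics of expanded HSC clades from single-colony phylogenies.

Colony trees arrive with branch lengths in somatic mutation counts. Because
HSCs accumulate mutations at a near-constant rate after birth — with a burst
of about 55 mutations between conception and birth — molecular depth maps to
age: the tree is made ultrametric, the 55-mutation depth is anchored at
birth, and deeper nodes are scaled linearly up to the age at sampling.

Expanded clades (driver-annotated, or with a long stem and >= 5 colonies)
are then analysed with a classic/generalized coalescent skyline: each
inter-coalescent interval with ``k`` lineages and duration ``dt`` years
estimates an effective population size ``N_eff = k (k - 1) dt / 2`` in units
of HSC x years (population size times generation time). A continuous
two-segment (biphasic) log-linear fit to the skyline yields early and late
growth rates; comparing extrapolated early growth with the observed clade
size, and the late rate with a logistic fit at fixed carrying capacity,
quantifies lifelong clonal deceleration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import least_squares

from clonekinetics.simulate import MutationTree

__all__ = [
    "TimeTree",
    "Clade",
    "NeffTrajectory",
    "BiphasicFit",
    "DecelerationReport",
    "scale_tree_to_time",
    "detect_clades",
    "skyline_neff",
    "skyline_from_intervals",
    "fit_biphasic",
    "deceleration_metrics",
]

DEFAULT_CONCEPTION = -0.75  # years before birth
DEFAULT_CAPACITY = 200_000.0  # HSC x years


@dataclass
class TimeTree:
    """Ultrametric colony phylogeny with node times in years.

    Times run from conception (default -0.75) through birth (0) to the age
    at sampling (all tips). Each node keeps its normalized molecular depth
    in ``node.mut_depth``; its time in ``node.time``.
    """

    tree: dendropy.Tree
    age_at_sampling: float
    conception: float = DEFAULT_CONCEPTION
    sensitivity: float = 1.0
    prebirth_mutations: float = 55.0
    driver_annotations: dict[str, str] = field(default_factory=dict)

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def time_depth(self) -> float:
        return self.age_at_sampling - self.conception

    def node_times(self) -> dict[str, float]:
        out = {}
        for nd in self.tree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else nd.label
            if label:
                out[label] = nd.time
        return out


def _node_label(nd) -> str | None:
    return nd.taxon.label if nd.taxon is not None else nd.label


def scale_tree_to_time(
    mtree: MutationTree,
    sensitivity: float = 1.0,
    conception: float = DEFAULT_CONCEPTION,
) -> TimeTree:
    """Time-calibrate a mutation-count tree.

    Branch lengths are corrected for variant-calling sensitivity (divided by
    ``sensitivity``), the tree is made ultrametric by proportional tip-path
    normalization (each node's depth is rescaled by the mean stretch factor
    of the tip paths through it), and molecular depth is mapped to age:
    the first ``prebirth_mutations`` span conception to birth, and depths
    beyond that scale linearly up to the age at sampling.
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must be in (0, 1]")
    if mtree.age_at_sampling <= 0:
        raise ValueError("age_at_sampling must be > 0")
    if mtree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    tree = mtree.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        if edge.length < 0:
            head = _node_label(edge.head_node) or "<unlabelled>"
            raise ValueError(f"negative branch length on branch above node {head!r}")
        edge.length = edge.length / sensitivity

    # raw molecular depths
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        nd.raw_depth = (parent.raw_depth if parent else 0.0) + (nd.edge.length or 0.0)

    tips = tree.leaf_nodes()
    tip_depths = np.array([nd.raw_depth for nd in tips], dtype=float)
    if np.any(tip_depths <= 0):
        raise ValueError("tip with zero molecular depth; tree cannot be calibrated")
    target = float(np.mean(tip_depths))

    # mean stretch factor of the tip paths through each node
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._stretch_sum = target / nd.raw_depth
            nd._tip_count = 1
        else:
            nd._stretch_sum = sum(ch._stretch_sum for ch in nd.child_nodes())
            nd._tip_count = sum(ch._tip_count for ch in nd.child_nodes())
    for nd in tree.preorder_node_iter():
        stretch = nd._stretch_sum / nd._tip_count
        nd.mut_depth = nd.raw_depth * stretch
    # enforce monotone depths root -> tip; tips sit exactly at the target
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        if parent is not None and nd.mut_depth < parent.mut_depth:
            nd.mut_depth = parent.mut_depth
        if nd.is_leaf():
            nd.mut_depth = target

    prebirth = mtree.prebirth_mutations
    if target <= prebirth:
        raise ValueError(
            f"mean tip depth {target:.1f} does not exceed the pre-birth "
            f"mutation count {prebirth}; cannot anchor birth"
        )
    age = mtree.age_at_sampling

    def to_time(depth: float) -> float:
        if depth >= prebirth:
            return (depth - prebirth) / (target - prebirth) * age
        return conception + (depth / prebirth) * (-conception)

    for nd in tree.preorder_node_iter():
        nd.time = to_time(nd.mut_depth)
        del nd._stretch_sum, nd._tip_count

    return TimeTree(
        tree=tree,
        age_at_sampling=age,
        conception=conception,
        sensitivity=sensitivity,
        prebirth_mutations=prebirth,
        driver_annotations=dict(mtree.driver_annotations),
    )


@dataclass
class Clade:
    """An expanded clade: colonies sharing an MRCA, with onset bounds given
    by the two ends of the branch leading to the MRCA."""

    tips: list[str]
    mrca_label: str | None
    onset_lower: float
    onset_upper: float
    clonal_fraction: float
    driver: str | None = None
    coalescent_times: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tips)


def detect_clades(
    ttree: TimeTree,
    min_tips: int = 5,
    depth_fraction: float = 0.1,
    drivers: dict[str, str] | None = None,
) -> list[Clade]:
    """Find maximal expanded clades in a calibrated tree.

    A clade qualifies if the branch leading to its MRCA carries a driver
    annotation, or if that stem branch spans more than ``depth_fraction`` of
    the tree's time depth and the clade holds at least ``min_tips`` colonies.
    Nested qualifying clades report only the outermost.
    """
    if drivers is None:
        drivers = ttree.driver_annotations
    total_tips = ttree.n_tips
    depth = ttree.time_depth
    clades: list[Clade] = []
    root = ttree.tree.seed_node

    def visit(nd, inside):
        qualify = False
        driver = None
        if nd is not root and not nd.is_leaf():
            label = _node_label(nd)
            driver = drivers.get(label) if label else None
            stem = nd.time - nd.parent_node.time
            n_below = len(nd.leaf_nodes())
            qualify = driver is not None or (
                stem > depth_fraction * depth and n_below >= min_tips
            )
        elif nd.is_leaf():
            label = _node_label(nd)
            driver = drivers.get(label) if label else None
            qualify = driver is not None
        if qualify and not inside:
            leaves = [nd] if nd.is_leaf() else nd.leaf_nodes()
            tips = [_node_label(lf) for lf in leaves]
            coal = np.sort([x.time for x in nd.preorder_iter() if not x.is_leaf()])
            clades.append(
                Clade(
                    tips=tips,
                    mrca_label=_node_label(nd),
                    onset_lower=float(nd.parent_node.time),
                    onset_upper=float(nd.time),
                    clonal_fraction=len(tips) / total_tips,
                    driver=driver,
                    coalescent_times=coal if coal.size else None,
                )
            )
            inside = True
        for ch in nd.child_nodes():
            visit(ch, inside)

    visit(root, False)
    return clades


# ---------------------------------------------------------------------------
# skyline effective population size
# ---------------------------------------------------------------------------


@dataclass
class NeffTrajectory:
    """Piecewise skyline estimate of N_eff (HSC x years) through time.

    ``variance`` is the exponential-interval-model variance of each pooled
    estimate, ``N_eff^2 / m`` for ``m`` pooled coalescent events;
    ``high_variance`` marks data-poor points (see :func:`skyline_from_intervals`).
    """

    times: np.ndarray
    neff: np.ndarray
    variance: np.ndarray
    n_events: np.ndarray
    high_variance: np.ndarray

    def __len__(self) -> int:
        return self.times.size


def skyline_from_intervals(
    coalescent_times: np.ndarray,
    sampling_time: float,
    n_tips: int,
    smoothing_epsilon: float = 0.0,
    min_events: int = 2,
    log_var_threshold: float | None = None,
) -> NeffTrajectory:
    """Classic/generalized skyline from homochronous coalescent times.

    Starting from ``n_tips`` lineages at ``sampling_time`` and moving into
    the past, each inter-coalescent interval of duration ``dt`` with ``k``
    extant lineages contributes ``N_eff = k (k - 1) dt / 2``. Adjacent
    intervals are pooled (generalized skyline) until each pool spans at
    least ``smoothing_epsilon`` years; a pooled estimate over ``m`` events
    is their contribution sum divided by ``m``, with variance
    ``N_eff^2 / m``. Points whose relative variance exceeds 1/``min_events``
    are flagged high-variance; pass ``log_var_threshold`` to instead flag
    where ``log(var(N_eff))`` exceeds the threshold.
    """
    coal = np.sort(np.asarray(coalescent_times, dtype=float))
    if coal.size < 1:
        raise ValueError("need at least 1 coalescent event (>= 2 tips)")
    if coal.size != n_tips - 1:
        raise ValueError(f"{n_tips} tips imply {n_tips - 1} coalescences, got {coal.size}")
    # walk backward: boundaries sampling_time, t_{m}, ..., t_1
    bounds = np.concatenate([[sampling_time], coal[::-1]])
    ks = np.arange(n_tips, 1, -1)  # lineages during each interval
    dts = bounds[:-1] - bounds[1:]
    contrib = ks * (ks - 1) * dts / 2.0
    mid = (bounds[:-1] + bounds[1:]) / 2.0

    times, neff, var, nev = [], [], [], []
    i = 0
    m_total = len(dts)
    while i < m_total:
        j = i + 1
        span = dts[i]
        while span < smoothing_epsilon and j < m_total:
            span += dts[j]
            j += 1
        m = j - i
        pooled = contrib[i:j].sum() / m
        w_mid = float(np.average(mid[i:j], weights=np.maximum(dts[i:j], 1e-12)))
        times.append(w_mid)
        neff.append(pooled)
        var.append(pooled**2 / m)
        nev.append(m)
        i = j
    times = np.asarray(times)[::-1]  # ascending (early -> late)
    neff = np.asarray(neff)[::-1]
    var = np.asarray(var)[::-1]
    nev = np.asarray(nev)[::-1]
    if log_var_threshold is not None:
        flags = np.log(np.maximum(var, 1e-300)) > log_var_threshold
    else:
        flags = nev < min_events
    return NeffTrajectory(
        times=times, neff=neff, variance=var, n_events=nev, high_variance=flags
    )


def skyline_neff(
    clade: Clade,
    ttree: TimeTree | None = None,
    smoothing_epsilon: float = 0.0,
    min_events: int = 2,
    log_var_threshold: float | None = None,
) -> NeffTrajectory:
    """Skyline N_eff trajectory for a detected clade."""
    if clade.coalescent_times is None or clade.coalescent_times.size < 1:
        raise ValueError("clade needs at least 1 coalescence (>= 2 tips)")
    sampling_time = ttree.age_at_sampling if ttree is not None else float(
        clade.coalescent_times.max()
    )
    return skyline_from_intervals(
        clade.coalescent_times,
        sampling_time,
        n_tips=clade.n_tips,
        smoothing_epsilon=smoothing_epsilon,
        min_events=min_events,
        log_var_threshold=log_var_threshold,
    )


# ---------------------------------------------------------------------------
# biphasic growth and deceleration
# ---------------------------------------------------------------------------


@dataclass
class BiphasicFit:
    """Continuous two-segment log-linear fit to a skyline trajectory."""

    breakpoint: float
    early_rate: float
    late_rate: float
    intercept: float  # value of log N_eff extrapolated to time 0 on the early segment
    sse: float

    def early_log_neff(self, time: float) -> float:
        return self.intercept + self.early_rate * time

    def fitted_log_neff(self, time: np.ndarray) -> np.ndarray:
        time = np.asarray(time, dtype=float)
        at_break = self.intercept + self.early_rate * self.breakpoint
        return np.where(
            time <= self.breakpoint,
            self.intercept + self.early_rate * time,
            at_break + self.late_rate * (time - self.breakpoint),
        )


def fit_biphasic(traj: NeffTrajectory, min_points: int = 2) -> BiphasicFit:
    """Fit a continuous biphasic exponential-growth model to log N_eff.

    High-variance points are excluded; the breakpoint is chosen by grid
    search over the observed interior time points (at least ``min_points``
    on each side), minimizing the sum of squared residuals; ties break to
    the earliest candidate.
    """
    usable = ~traj.high_variance
    if not np.any(usable):
        raise ValueError("all skyline points are flagged high-variance")
    t = traj.times[usable]
    y = np.log(traj.neff[usable])
    order = np.argsort(t)
    t, y = t[order], y[order]
    if t.size < 2 * min_points:
        raise ValueError(f"need at least {2 * min_points} usable points")

    best = None
    for idx in range(min_points - 1, t.size - min_points):
        tau = t[idx]
        basis = np.column_stack([np.ones_like(t), t, np.maximum(t - tau, 0.0)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, tau, coef)
    sse, tau, coef = best
    a, r1, dr = coef
    return BiphasicFit(
        breakpoint=float(tau),
        early_rate=float(r1),
        late_rate=float(r1 + dr),
        intercept=float(a),
        sse=sse,
    )


@dataclass
class DecelerationReport:
    """Observed-vs-expected clone size and growth ratios for one clade.

    ``size_ratio`` < 1 means the clade is smaller than early growth
    extrapolated to the sampling age predicts; ``growth_ratio`` < 1 means
    late growth is slower than a constant-rate logistic expansion at fixed
    carrying capacity would require. Both equal to 1 means no deceleration.
    """

    expected_size: float
    observed_size: float
    size_ratio: float
    expected_growth: float
    growth_ratio: float
    log_expected_size: float
    log_observed_size: float


def _logistic_growth_fit(
    times: np.ndarray, neff: np.ndarray, capacity: float, init_rate: float
) -> float:
    """Growth coefficient of a logistic N(t) = K / (1 + exp(-r (t - t0)))
    fitted to the trajectory on the log scale with K fixed."""
    logn = np.log(np.minimum(neff, capacity * (1 - 1e-9)))
    # initial midpoint: where the trajectory crosses K/2, else the last time
    below = neff < capacity / 2
    t0_init = float(times[below][-1]) if np.any(below) else float(times[-1])

    def resid(params):
        r, t0 = params
        return np.log(capacity) - np.logaddexp(0.0, -r * (times - t0)) - logn

    sol = least_squares(
        resid, x0=[max(init_rate, 1e-3), t0_init], max_nfev=10_000
    )
    return float(sol.x[0])


def deceleration_metrics(
    fit: BiphasicFit,
    clade: Clade,
    traj: NeffTrajectory | None = None,
    capacity: float = DEFAULT_CAPACITY,
    sampling_age: float | None = None,
) -> DecelerationReport:
    """Quantify clonal deceleration for a clade.

    Expected size extrapolates the early-segment growth to the sampling
    age; observed size is the clade's tip fraction times the carrying
    capacity (in HSC x years). Expected growth is the rate of a logistic
    fit to the N_eff trajectory at fixed capacity; the growth ratio is
    late / expected. Ratios are computed in log space to avoid overflow.
    """
    if sampling_age is None:
        raise ValueError("sampling_age is required")
    log_expected = fit.early_log_neff(sampling_age)
    observed = clade.clonal_fraction * capacity
    if observed <= 0:
        raise ValueError("clade has zero clonal fraction")
    log_observed = math.log(observed)
    log_ratio = log_observed - log_expected
    size_ratio = math.exp(log_ratio) if abs(log_ratio) < 700 else (
        0.0 if log_ratio < 0 else math.inf
    )
    if traj is not None and len(traj) >= 3:
        usable = ~traj.high_variance
        expected_growth = _logistic_growth_fit(
            traj.times[usable], traj.neff[usable], capacity, fit.early_rate
        )
    else:
        expected_growth = fit.early_rate
    growth_ratio = fit.late_rate / expected_growth if expected_growth != 0 else math.nan
    return DecelerationReport(
        expected_size=math.exp(log_expected) if log_expected < 700 else math.inf,
        observed_size=observed,
        size_ratio=size_ratio,
        expected_growth=expected_growth,
        growth_ratio=growth_ratio,
        log_expected_size=log_expected,
        log_observed_size=log_observed,
    )
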