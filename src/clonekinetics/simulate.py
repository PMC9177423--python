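"""Synthetic cohorts: Wright-Fisher clone histories, sequencing counts, and colony trees.

The generator emulates the data the downstream analyses consume:

* haematopoietic stem-cell (HSC) clones growing under a discrete Wright-Fisher
  model with per-driver selection coefficients,
* longitudinal deep-sequencing variant counts drawn beta-binomially around the
  heterozygous allele fraction of each clone at scheduled ages,
* technical replicate sets for calibrating sequencing overdispersion, and
* single-cell-derived colony phylogenies sampled from the simulated population
  by a backward within-clone coalescent, with Poisson mutation accumulation
  and a burst of pre-birth mutations.

Every operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Driver",
    "WFConfig",
    "WFHistory",
    "LongitudinalDataset",
    "ReplicateSet",
    "MutationTree",
    "simulate_wf",
    "simulate_wf_conditioned",
    "sample_sequencing",
    "generate_replicates",
    "sample_colony_tree",
]

LONGITUDINAL_COLUMNS = [
    "individual_id",
    "clone_id",
    "gene",
    "site",
    "consequence",
    "age_years",
    "depth",
    "alt_count",
]


@dataclass(frozen=True)
class Driver:
    """A driver mutation and the selective advantage it confers.

    ``fitness`` is the per-generation selection coefficient ``s``: a mutant
    cell leaves ``(1 + s)`` offspring for every wild-type offspring in
    expectation. ``fitness_schedule`` optionally changes ``s`` during life,
    as ``((generation, new_s), ...)`` breakpoints, to emulate clones whose
    advantage wanes (e.g. through a changing competitive landscape).
    """

    label: str
    fitness: float
    onset_generation: int
    gene: str = ""
    site: str = ""
    consequence: str = "missense"
    fitness_schedule: tuple[tuple[int, float], ...] = ()
    initial_cells: int = 1

    def __post_init__(self):
        if not self.label:
            raise ValueError("driver label must be non-empty")
        if self.fitness <= -1:
            raise ValueError("fitness s must be > -1")
        if self.initial_cells < 1:
            raise ValueError("initial_cells must be >= 1")
        if not self.gene:
            object.__setattr__(self, "gene", self.label.split(":")[0])

    def fitness_at(self, generation: int) -> float:
        s = self.fitness
        for gen, new_s in self.fitness_schedule:
            if generation >= gen:
                s = new_s
        return s


@dataclass(frozen=True)
class WFConfig:
    """Configuration of a Wright-Fisher HSC population.

    Defaults follow the field's standard HSC parameter estimates: a
    population of 50,000 stem cells turning over twice a year.
    """

    n_hsc: int = 50_000
    generations_per_year: float = 2.0
    drivers: tuple[Driver, ...] = ()
    total_years: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if self.n_hsc < 10:
            raise ValueError("n_hsc must be >= 10")
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be > 0")
        if self.total_years <= 0:
            raise ValueError("total_years must be > 0")
        n_gen = self.n_generations
        for d in self.drivers:
            if not (0 <= d.onset_generation <= n_gen):
                raise ValueError(
                    f"driver {d.label!r}: onset_generation {d.onset_generation} "
                    f"outside [0, {n_gen}]"
                )
        labels = [d.label for d in self.drivers]
        if len(set(labels)) != len(labels):
            raise ValueError("driver labels must be unique")
        if sum(d.initial_cells for d in self.drivers) >= self.n_hsc:
            raise ValueError("summed initial clone cells exceed n_hsc")

    @property
    def n_generations(self) -> int:
        return int(round(self.total_years * self.generations_per_year))


@dataclass
class WFHistory:
    """Per-generation clone fractions from one Wright-Fisher run.

    ``fractions`` has shape ``(n_drivers, n_generations + 1)``; column ``t``
    holds the clone fraction after ``t`` generations of resampling. All
    values are multiples of ``1 / n_hsc``. ``established[i]`` is True iff
    driver ``i`` is still segregating (fraction > 0) at the final generation.
    """

    config: WFConfig
    fractions: np.ndarray
    established: np.ndarray

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.fractions.shape[1])

    @property
    def ages(self) -> np.ndarray:
        return self.generations / self.config.generations_per_year

    def fraction_at_age(self, age: float, driver_index: int = 0) -> float:
        """Clone fraction at the generation closest to ``age`` years."""
        gen = int(round(age * self.config.generations_per_year))
        gen = min(max(gen, 0), self.fractions.shape[1] - 1)
        return float(self.fractions[driver_index, gen])


def simulate_wf(config: WFConfig, rng: np.random.Generator | None = None) -> WFHistory:
    """Run one forward Wright-Fisher simulation.

    Each generation the ``n_hsc`` cells are resampled multinomially with
    per-clone weights proportional to ``count * (1 + s)``. A driver clone is
    seeded with a single cell at its onset generation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_hsc
    n_gen = config.n_generations
    drivers = config.drivers
    n_d = len(drivers)
    counts = np.zeros(n_d, dtype=np.int64)  # mutant-cell counts; wild type implicit
    fractions = np.zeros((n_d, n_gen + 1))
    onset = np.array([d.onset_generation for d in drivers], dtype=np.int64)

    init_cells = np.array([d.initial_cells for d in drivers], dtype=np.int64)
    for d_idx in np.flatnonzero(onset == 0):
        counts[d_idx] = init_cells[d_idx]
    fractions[:, 0] = counts / n

    for t in range(1, n_gen + 1):
        if counts.sum() > 0:
            s = np.array([d.fitness_at(t - 1) for d in drivers])
            w_mut = counts * (1.0 + s)
            w_wt = n - counts.sum()
            total = w_mut.sum() + w_wt
            p = np.concatenate([w_mut / total, [w_wt / total]])
            new = rng.multinomial(n, p)
            counts = new[:n_d]
        newly = np.flatnonzero(onset == t)
        if newly.size:
            free = n - counts.sum()
            if free < init_cells[newly].sum():
                raise ValueError("no wild-type cells left to seed new clone")
            counts[newly] = np.maximum(counts[newly], init_cells[newly])
        fractions[:, t] = counts / n

    established = fractions[:, -1] > 0 if n_d else np.zeros(0, dtype=bool)
    return WFHistory(config=config, fractions=fractions, established=np.asarray(established))


def simulate_wf_conditioned(
    config: WFConfig,
    driver_index: int = 0,
    max_tries: int = 10_000,
) -> WFHistory:
    """Rerun :func:`simulate_wf` until the given driver clone establishes.

    New-mutant lineages usually die out by drift; analyses of observed clones
    implicitly condition on survival, which this helper makes explicit.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(max_tries):
        hist = simulate_wf(config, rng=rng)
        if hist.established[driver_index]:
            return hist
    raise RuntimeError(f"clone failed to establish in {max_tries} tries")


# ---------------------------------------------------------------------------
# longitudinal sequencing data
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalDataset:
    """Serial sequencing observations, one row per (clone, timepoint).

    ``df`` columns: individual_id, clone_id, gene, site, consequence,
    age_years, depth, alt_count. ``truth`` (optional, simulation only) has
    one row per clone: clone_id, b_total, u, onset_age.
    """

    df: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in LONGITUDINAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.df["alt_count"] > self.df["depth"]).any():
            raise ValueError("alt_count exceeds depth")
        if (self.df["alt_count"] < 0).any() or (self.df["depth"] < 1).any():
            raise ValueError("counts must be non-negative and depth >= 1")

    @property
    def clone_ids(self) -> list[str]:
        return list(self.df["clone_id"].unique())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LongitudinalDataset":
        df = pd.read_csv(path, sep="\t", dtype={"site": str})
        df["site"] = df["site"].fillna("")
        return cls(df=df)

    def concat(self, other: "LongitudinalDataset") -> "LongitudinalDataset":
        truth = None
        if self.truth is not None and other.truth is not None:
            truth = pd.concat([self.truth, other.truth], ignore_index=True)
        return LongitudinalDataset(
            df=pd.concat([self.df, other.df], ignore_index=True), truth=truth
        )


def _betabinom_draw(rng, depth, q, beta_od):
    """One beta-binomial draw with mean ``depth * q`` and concentration set
    by ``alpha = beta_od * q / (1 - q)``; the binomial limit as beta_od -> inf."""
    if q <= 0:
        return 0
    if q >= 1:
        raise ValueError("allele fraction q must be < 1")
    if not np.isfinite(beta_od):
        return int(rng.binomial(depth, q))
    alpha = beta_od * q / (1.0 - q)
    p = rng.beta(alpha, beta_od)
    return int(rng.binomial(depth, p))


def sample_sequencing(
    history: WFHistory,
    schedule: list[float],
    depth: int,
    beta_od: float,
    seed: int,
    individual_id: str = "sim_01",
) -> LongitudinalDataset:
    """Draw longitudinal variant counts from a Wright-Fisher history.

    At each scheduled age, each driver clone at fraction ``f`` is sequenced
    as a heterozygous mutation with allele fraction ``q = f / 2``; the
    variant read count is beta-binomial around ``q`` with technical
    concentration ``beta_od``. Truth rows record the annual logit-scale
    growth implied by the driver's fitness, ``b = g * log(1 + s)``, and the
    offset ``u`` anchored at the last scheduled age.
    """
    cfg = history.config
    if depth < 1:
        raise ValueError("depth must be >= 1")
    schedule = sorted(float(a) for a in schedule)
    if schedule and (schedule[0] < 0 or schedule[-1] > cfg.total_years + 1e-9):
        raise ValueError("schedule outside simulated span")
    if len(set(schedule)) < len(schedule):
        raise ValueError("ages must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    g = cfg.generations_per_year
    for i, drv in enumerate(cfg.drivers):
        clone_id = f"{individual_id}:{drv.label}"
        for age in schedule:
            f = history.fraction_at_age(age, i)
            q = f / 2.0
            alt = _betabinom_draw(rng, depth, q, beta_od)
            rows.append(
                (individual_id, clone_id, drv.gene, drv.site, drv.consequence,
                 age, depth, alt)
            )
        b_true = g * math.log1p(drv.fitness)
        f_last = history.fraction_at_age(schedule[-1], i) if schedule else 0.0
        q_last = min(max(f_last / 2.0, 1e-12), 1 - 1e-12)
        u_true = math.log(q_last / (1 - q_last)) - b_true * (schedule[-1] if schedule else 0.0)
        truth_rows.append((clone_id, b_true, u_true, drv.onset_generation / g))
    df = pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["clone_id", "b_total", "u", "onset_age"])
    return LongitudinalDataset(df=df, truth=truth)


def sample_model_cohort(
    gene_effects: dict[str, float],
    clones_per_gene: int,
    ages: list[float],
    depth: int,
    beta_od: float,
    seed: int,
    clone_sd: float = 0.05,
    last_vaf_range: tuple[float, float] = (0.05, 0.35),
    center_clone_effects: bool = True,
) -> LongitudinalDataset:
    """Draw a cohort directly from the hierarchical observation model.

    Each gene contributes ``clones_per_gene`` clones whose total growth is the
    gene effect plus a per-clone effect ~ N(0, clone_sd); with
    ``center_clone_effects`` the per-clone effects are centred within each
    gene so the gene effect equals the cohort-mean growth by construction.
    Offsets are set so the expected VAF at the final age is uniform in
    ``last_vaf_range``. Counts are beta-binomial around the logistic
    trajectory. Truth columns record b_total, u and the gene effect.
    """
    from scipy.special import expit, logit as _logit

    rng = np.random.default_rng(seed)
    ages = sorted(float(a) for a in ages)
    rows, truth_rows = [], []
    ind = 0
    for gene, bg in gene_effects.items():
        bcs = rng.normal(0.0, clone_sd, size=clones_per_gene)
        if center_clone_effects and clones_per_gene > 1:
            bcs = bcs - bcs.mean()
        for j in range(clones_per_gene):
            b = bg + bcs[j]
            q_last = rng.uniform(*last_vaf_range)
            u = float(_logit(q_last)) - b * ages[-1]
            cid = f"{gene}_c{j:02d}"
            for a in ages:
                q = float(expit(b * a + u))
                rows.append(
                    (f"ind_{ind:03d}", cid, gene, "", "missense", a, depth,
                     _betabinom_draw(rng, depth, q, beta_od))
                )
            truth_rows.append((cid, b, u, float("nan")))
            ind += 1
    df = pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["clone_id", "b_total", "u", "onset_age"])
    return LongitudinalDataset(df=df, truth=truth)


# ---------------------------------------------------------------------------
# replicate calibration sets
# ---------------------------------------------------------------------------

DILUTION_SERIES_VAFS = (0.05, 0.02, 0.01, 0.005, 0.0)


@dataclass
class ReplicateSet:
    """Technical replicate groups sharing one true VAF per group.

    ``df`` columns: group_id, depth, alt_count; ``true_vafs`` maps group_id
    to the shared underlying VAF; ``true_beta`` is the generating
    beta-binomial concentration (None for real data).
    """

    df: pd.DataFrame
    true_vafs: dict[str, float] = field(default_factory=dict)
    true_beta: float | None = None

    def __post_init__(self):
        sizes = self.df.groupby("group_id").size()
        if (sizes < 2).any():
            raise ValueError("every replicate group needs k >= 2 members")

    @property
    def n_groups(self) -> int:
        return self.df["group_id"].nunique()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReplicateSet":
        return cls(df=pd.read_csv(path, sep="\t"))


def generate_replicates(
    vafs: list[float],
    depth: int,
    beta_od: float,
    k: int,
    seed: int,
    groups_per_vaf: int = 1,
) -> ReplicateSet:
    """Generate replicate groups: ``k`` beta-binomial draws at each shared VAF.

    The default dilution series of the calibration experiment is available
    as :data:`DILUTION_SERIES_VAFS` (a zero-VAF group draws all-zero counts).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if any(v < 0 or v >= 1 for v in vafs):
        raise ValueError("vafs must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    true_vafs = {}
    gid = 0
    for v in vafs:
        for _ in range(groups_per_vaf):
            group = f"g{gid:04d}"
            gid += 1
            true_vafs[group] = v
            for _r in range(k):
                rows.append((group, depth, _betabinom_draw(rng, depth, v, beta_od)))
    df = pd.DataFrame(rows, columns=["group_id", "depth", "alt_count"])
    return ReplicateSet(df=df, true_vafs=true_vafs, true_beta=beta_od)


# ---------------------------------------------------------------------------
# colony phylogenies
# ---------------------------------------------------------------------------


@dataclass
class MutationTree:
    """Rooted colony phylogeny with branch lengths in somatic mutation counts.

    ``driver_annotations`` maps the label of the node *below* a branch to the
    driver carried by that branch. ``clone_tips`` (simulation truth) maps the
    driver label to the colony labels inside the clone.
    """

    tree: dendropy.Tree
    age_at_sampling: float
    mutation_rate_per_year: float
    prebirth_mutations: float = 55.0
    driver_annotations: dict[str, str] = field(default_factory=dict)
    clone_tips: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def write(self, newick_path, meta_path=None, drivers_path=None) -> None:
        self.tree.write(path=str(newick_path), schema="newick",
                        suppress_rooting=True)
        if meta_path is not None:
            meta = {
                "age_at_sampling": float(self.age_at_sampling),
                "mutation_rate_per_year": float(self.mutation_rate_per_year),
                "prebirth_mutations": float(self.prebirth_mutations),
            }
            with open(meta_path, "w") as fh:
                yaml.safe_dump(meta, fh)
        if drivers_path is not None:
            pd.DataFrame(
                [(node, drv) for node, drv in sorted(self.driver_annotations.items())],
                columns=["node_label", "driver"],
            ).to_csv(drivers_path, sep="\t", index=False)

    @classmethod
    def read(cls, newick_path, meta_path, drivers_path=None) -> "MutationTree":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                                 preserve_underscores=True)
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        ann = {}
        if drivers_path is not None:
            dd = pd.read_csv(drivers_path, sep="\t")
            ann = dict(zip(dd["node_label"].astype(str), dd["driver"].astype(str)))
        return cls(
            tree=tree,
            age_at_sampling=float(meta["age_at_sampling"]),
            mutation_rate_per_year=float(meta["mutation_rate_per_year"]),
            prebirth_mutations=float(meta.get("prebirth_mutations", 55.0)),
            driver_annotations=ann,
        )


class _Lineage:
    __slots__ = ("node", "entry_time")

    def __init__(self, node, entry_time):
        self.node = node
        self.entry_time = entry_time


def _coalesce_step(rng, lineages, pop_size, time):
    """One backward time-step of the within-population coalescent: merge
    random pairs while the pairwise rate k(k-1)/(2N) keeps firing."""
    merged = []
    while len(lineages) > 1:
        k = len(lineages)
        p = k * (k - 1) / (2.0 * max(pop_size, 1.0))
        if p < 1.0 and rng.random() >= p:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a = lineages[max(i, j)]
        b = lineages[min(i, j)]
        lineages.remove(a)
        lineages.remove(b)
        parent = dendropy.Node()
        parent.add_child(a.node)
        parent.add_child(b.node)
        parent.time = time
        lineages.append(_Lineage(parent, time))
        merged.append(parent)
        if p < 1.0:
            break
    return merged


def sample_colony_tree(
    history: WFHistory,
    n_colonies: int,
    mutation_rate_per_year: float,
    prebirth_mutations: float = 55.0,
    seed: int = 0,
    conception: float = -0.75,
) -> MutationTree:
    """Sample a single-cell-colony phylogeny from a Wright-Fisher history.

    Colonies are drawn at the end of the simulation with probabilities equal
    to the final clone fractions (wild type takes the remainder). Genealogies
    are built backward in time: within each clone, lineages coalesce under a
    piecewise population size read off the clone's recorded history, meeting
    in the founder cell at the clone's onset; founder lineages and wild-type
    colonies then coalesce in the background population, and any lineages
    still distinct at birth coalesce during the fetal expansion from a single
    cell at conception. Branch lengths are Poisson mutation counts at
    ``mutation_rate_per_year`` after birth, with ``prebirth_mutations``
    expected on the conception-to-birth segment. Assumes single-cell clone
    origins (drivers seeded with ``initial_cells=1``).
    """
    cfg = history.config
    if n_colonies < 2:
        raise ValueError("n_colonies must be >= 2")
    if n_colonies > cfg.n_hsc:
        raise ValueError("n_colonies exceeds n_hsc")
    rng = np.random.default_rng(seed)
    g = cfg.generations_per_year
    n_gen = cfg.n_generations
    age = cfg.total_years
    n_d = len(cfg.drivers)

    final_f = history.fractions[:, -1] if n_d else np.zeros(0)
    probs = np.concatenate([final_f, [max(1.0 - final_f.sum(), 0.0)]])
    probs = probs / probs.sum()
    tip_counts = rng.multinomial(n_colonies, probs)

    taxon_namespace = dendropy.TaxonNamespace()
    tip_nodes: list[dendropy.Node] = []
    clone_lineages: dict[int, list[_Lineage]] = {i: [] for i in range(n_d)}
    wt_lineages: list[_Lineage] = []
    clone_tips: dict[str, list[str]] = {d.label: [] for d in cfg.drivers}
    tip_i = 0
    for group_idx, count in enumerate(tip_counts):
        for _ in range(count):
            label = f"colony_{tip_i:04d}"
            tip_i += 1
            taxon = taxon_namespace.new_taxon(label)
            node = dendropy.Node(taxon=taxon)
            node.time = age
            lin = _Lineage(node, age)
            tip_nodes.append(node)
            if group_idx < n_d:
                clone_lineages[group_idx].append(lin)
                clone_tips[cfg.drivers[group_idx].label].append(label)
            else:
                wt_lineages.append(lin)

    driver_annotations: dict[str, str] = {}
    internal_counter = [0]

    def _label(node):
        if node.taxon is None and node.label is None:
            internal_counter[0] += 1
            node.label = f"n{internal_counter[0]:04d}"
        return node.label or node.taxon.label

    # backward through postnatal generations
    for t in range(n_gen, 0, -1):
        time = t / g
        for i in range(n_d):
            lins = clone_lineages[i]
            if len(lins) > 1:
                clone_cells = history.fractions[i, t] * cfg.n_hsc
                _coalesce_step(rng, lins, clone_cells, time)
            drv = cfg.drivers[i]
            if t == drv.onset_generation and lins:
                # all surviving clone lineages meet in the founder cell
                while len(lins) > 1:
                    _coalesce_step(rng, lins, 1.0, time)
                founder = lins.pop()
                founder_node = founder.node
                driver_annotations[_label(founder_node)] = drv.label
                wt_lineages.append(_Lineage(founder_node, time))
        if len(wt_lineages) > 1:
            wt_cells = cfg.n_hsc * max(1.0 - history.fractions[:, t].sum() if n_d else 1.0, 1e-9)
            _coalesce_step(rng, wt_lineages, wt_cells, time)

    # clones with onset at generation 0 that never merged into wild type
    for i in range(n_d):
        lins = clone_lineages[i]
        while len(lins) > 1:
            _coalesce_step(rng, lins, 1.0, 0.0)
        if lins:
            node = lins.pop().node
            driver_annotations[_label(node)] = cfg.drivers[i].label
            wt_lineages.append(_Lineage(node, 0.0))

    # fetal expansion: population grows from 1 cell at conception to n_hsc at
    # birth; step backward on a fine grid with the linearly shrinking size
    span = -conception
    n_steps = 200
    dt = span / n_steps
    for step in range(n_steps):
        if len(wt_lineages) <= 1:
            break
        time = -step * dt / 1.0  # from 0 toward conception
        frac = 1.0 - (step + 0.5) / n_steps
        pop = max(cfg.n_hsc * frac, 1.0)
        # rate per step scales with dt relative to the ~weekly fetal division time
        eff_pop = pop * (0.02 / dt) if dt > 0.02 else pop
        _coalesce_step(rng, wt_lineages, eff_pop, time - dt)
    while len(wt_lineages) > 1:
        _coalesce_step(rng, wt_lineages, 1.0, conception)

    root = wt_lineages[0].node
    if root.time > conception:
        # hang the sampled root below a conception-time origin
        origin = dendropy.Node()
        origin.time = conception
        origin.add_child(root)
        root = origin

    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = True

    prebirth_rate = prebirth_mutations / span
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = 0.0
            continue
        t_par = node.parent_node.time
        t_child = node.time
        post = max(t_child, 0.0) - max(t_par, 0.0)
        pre = min(t_child, 0.0) - min(t_par, 0.0)
        mean = mutation_rate_per_year * post + prebirth_rate * pre
        node.edge.length = float(rng.poisson(max(mean, 0.0)))
        _label(node)

    return MutationTree(
        tree=tree,
        age_at_sampling=age,
        mutation_rate_per_year=mutation_rate_per_year,
        prebirth_mutations=prebirth_mutations,
        driver_annotations=driver_annotations,
        clone_tips=clone_tips,
    )
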