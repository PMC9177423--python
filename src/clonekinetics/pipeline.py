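"""Pipeline orchestration: configuration, input validation, and staged runs.

``run_pipeline`` executes simulate -> fit -> onset -> phylodynamics ->
report on a configured synthetic cohort (or user-supplied tables/trees),
writing every stage's outputs plus a manifest that makes the run fully
reproducible from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from clonekinetics.model import (
    MCMCConfig,
    OverdispersionEstimate,
    estimate_overdispersion,
    fit_trajectories,
    flag_outliers,
)
from clonekinetics.onset import onset_table
from clonekinetics.phylo import (
    deceleration_metrics,
    detect_clades,
    fit_biphasic,
    scale_tree_to_time,
    skyline_neff,
)
from clonekinetics.simulate import (
    LONGITUDINAL_COLUMNS,
    Driver,
    LongitudinalDataset,
    MutationTree,
    WFConfig,
    generate_replicates,
    sample_colony_tree,
    sample_sequencing,
    simulate_wf_conditioned,
)

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML round-trippable.

    Stage toggles let any downstream stage be skipped. All model constants
    are exposed; every stochastic stage derives its own logged seed from
    ``master_seed``.
    """

    # model constants
    n_hsc: int = 50_000
    generations_per_year: float = 2.0
    capacity: float = 200_000.0
    prebirth_mutations: float = 55.0
    conception_tree: float = -0.75
    conception_onset: float = -1.0
    detection_threshold_vaf: float = 0.002
    outlier_cutoff: float = 0.025
    hpdi_mass: float = 0.90
    vaf_ceiling: float = 1.0
    # synthetic cohort
    simulate: bool = True
    n_individuals: int = 3
    drivers_per_individual: int = 2
    fitness_grid: tuple[float, ...] = (0.05, 0.1)
    onset_age: float = 25.0
    total_years: float = 75.0
    schedule: tuple[float, ...] = (55.0, 60.0, 65.0, 70.0, 75.0)
    depth: int = 2000
    beta_od_truth: float = 120.0
    n_colonies: int = 60
    mutation_rate_per_year: float = 18.0
    # replicate calibration
    replicate_vafs: tuple[float, ...] = (0.05, 0.02, 0.01, 0.005)
    replicate_groups_per_vaf: int = 6
    replicate_k: int = 3
    replicate_depth: int = 2000
    # stage toggles
    run_fit: bool = True
    run_onset: bool = True
    run_phylo: bool = True
    # inputs when simulate is False
    longitudinal_tsv: str | None = None
    replicates_tsv: str | None = None
    tree_newick: str | None = None
    tree_meta_yaml: str | None = None
    tree_drivers_tsv: str | None = None
    # MCMC
    mcmc_iterations: int = 2000
    mcmc_chains: int = 2
    mcmc_leapfrog_steps: int = 40
    master_seed: int = 1

    def mcmc(self, seed: int) -> MCMCConfig:
        return MCMCConfig(
            iterations=self.mcmc_iterations,
            chains=self.mcmc_chains,
            leapfrog_steps=self.mcmc_leapfrog_steps,
            seed=seed,
            vaf_ceiling=self.vaf_ceiling,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fitness_grid", "schedule", "replicate_vafs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _validate_longitudinal(path, errors: list[str]) -> None:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        errors.append(f"{path}: unreadable TSV ({exc})")
        return
    missing = [c for c in LONGITUDINAL_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"{path}: missing columns {missing}")
        return
    for col in ("depth", "alt_count"):
        if not pd.api.types.is_integer_dtype(df[col]):
            errors.append(f"{path}: column {col} must be integer")
    bad = df.index[df["alt_count"] > df["depth"]]
    for i in bad:
        errors.append(f"{path}: row {i}: alt_count > depth")
    for cid, sub in df.groupby("clone_id"):
        ages = sub["age_years"].to_numpy()
        if len(ages) < 2:
            errors.append(f"{path}: clone {cid}: fewer than 2 timepoints")
        if not np.all(np.diff(ages) > 0):
            errors.append(f"{path}: clone {cid}: ages not strictly increasing")


def _validate_tree(newick, meta, errors: list[str]) -> None:
    try:
        tree = dendropy.Tree.get(path=str(newick), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"{newick}: unparseable Newick ({exc})")
        return
    if len(tree.leaf_nodes()) < 2:
        errors.append(f"{newick}: fewer than 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            head = edge.head_node
            label = head.taxon.label if head.taxon else (head.label or "<internal>")
            errors.append(f"{newick}: negative branch length above node {label}")
    if meta is not None:
        try:
            with open(meta) as fh:
                m = yaml.safe_load(fh)
            for key in ("age_at_sampling", "mutation_rate_per_year"):
                if key not in m:
                    errors.append(f"{meta}: missing key {key}")
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{meta}: unreadable metadata ({exc})")


def validate_inputs(
    longitudinal_tsv=None,
    replicates_tsv=None,
    tree_newick=None,
    tree_meta_yaml=None,
) -> ValidationReport:
    """Schema-check pipeline inputs; all problems are enumerated, not thrown
    one at a time."""
    errors: list[str] = []
    for path in (longitudinal_tsv, replicates_tsv, tree_newick, tree_meta_yaml):
        if path is not None and not Path(path).exists():
            errors.append(f"{path}: file not found")
    if longitudinal_tsv and Path(longitudinal_tsv).exists():
        _validate_longitudinal(longitudinal_tsv, errors)
    if replicates_tsv and Path(replicates_tsv).exists():
        try:
            rdf = pd.read_csv(replicates_tsv, sep="\t")
            missing = [c for c in ("group_id", "depth", "alt_count") if c not in rdf.columns]
            if missing:
                errors.append(f"{replicates_tsv}: missing columns {missing}")
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{replicates_tsv}: unreadable TSV ({exc})")
    if tree_newick and Path(tree_newick).exists():
        meta = tree_meta_yaml if tree_meta_yaml and Path(tree_meta_yaml).exists() else None
        _validate_tree(tree_newick, meta, errors)
    return ValidationReport(errors=errors)


def _simulate_cohort(cfg: PipelineConfig, seeds):
    """Build the synthetic cohort: per-individual WF histories with
    established clones, sequencing tables, replicates, and one colony tree."""
    rng = np.random.default_rng(seeds["simulate"])
    datasets = []
    histories = []
    onset_gen = int(round(cfg.onset_age * cfg.generations_per_year))
    genes = ["DNMT3A", "TET2", "SRSF2", "SF3B1", "TP53", "U2AF1"]
    for ind in range(cfg.n_individuals):
        drivers = []
        for d in range(cfg.drivers_per_individual):
            s = cfg.fitness_grid[(ind * cfg.drivers_per_individual + d) % len(cfg.fitness_grid)]
            gene = genes[(ind * cfg.drivers_per_individual + d) % len(genes)]
            drivers.append(
                Driver(
                    label=f"{gene}_i{ind}d{d}",
                    gene=gene,
                    site=f"s{d}",
                    fitness=s,
                    onset_generation=onset_gen + 10 * d,
                )
            )
        wf_cfg = WFConfig(
            n_hsc=cfg.n_hsc,
            generations_per_year=cfg.generations_per_year,
            drivers=tuple(drivers),
            total_years=cfg.total_years,
            seed=int(rng.integers(2**31 - 1)),
        )
        hist = simulate_wf_conditioned(wf_cfg, driver_index=0)
        histories.append(hist)
        datasets.append(
            sample_sequencing(
                hist,
                list(cfg.schedule),
                depth=cfg.depth,
                beta_od=cfg.beta_od_truth,
                seed=int(rng.integers(2**31 - 1)),
                individual_id=f"ind_{ind:02d}",
            )
        )
    data = datasets[0]
    for d in datasets[1:]:
        data = data.concat(d)
    replicates = generate_replicates(
        list(cfg.replicate_vafs),
        depth=cfg.replicate_depth,
        beta_od=cfg.beta_od_truth,
        k=cfg.replicate_k,
        seed=seeds["replicates"],
        groups_per_vaf=cfg.replicate_groups_per_vaf,
    )
    tree = sample_colony_tree(
        histories[0],
        n_colonies=cfg.n_colonies,
        mutation_rate_per_year=cfg.mutation_rate_per_year,
        prebirth_mutations=cfg.prebirth_mutations,
        seed=seeds["tree"],
        conception=cfg.conception_tree,
    )
    return data, replicates, tree


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the configured stages, writing all artifacts under ``outdir``.

    Stage failures raise with the stage name; outputs of completed stages
    are left in place.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(6)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["simulate", "replicates", "tree", "od_mcmc", "fit_mcmc", "extra"], children
        )
    }
    from clonekinetics import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages_run": [],
    }

    def _fail(stage, exc):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    data = replicates = mtree = None
    try:
        if config.simulate:
            data, replicates, mtree = _simulate_cohort(config, seeds)
            data.to_tsv(out / "longitudinal.tsv")
            replicates.to_tsv(out / "replicates.tsv")
            mtree.write(out / "tree.nwk", out / "tree_meta.yaml", out / "tree_drivers.tsv")
            if data.truth is not None:
                data.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        else:
            report = validate_inputs(
                config.longitudinal_tsv,
                config.replicates_tsv,
                config.tree_newick,
                config.tree_meta_yaml,
            )
            if not report.ok:
                raise ValueError("input validation failed: " + "; ".join(report.errors))
            if config.longitudinal_tsv:
                data = LongitudinalDataset.from_tsv(config.longitudinal_tsv)
            if config.replicates_tsv:
                from clonekinetics.simulate import ReplicateSet

                replicates = ReplicateSet.from_tsv(config.replicates_tsv)
            if config.tree_newick:
                mtree = MutationTree.read(
                    config.tree_newick, config.tree_meta_yaml, config.tree_drivers_tsv
                )
        manifest["stages_run"].append("simulate" if config.simulate else "load")
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)

    fit = None
    summary: dict = {}
    if config.run_fit and data is not None:
        try:
            if replicates is not None:
                od = estimate_overdispersion(
                    replicates,
                    mode="dilution",
                    mcmc=MCMCConfig(
                        iterations=max(config.mcmc_iterations, 2000),
                        chains=config.mcmc_chains,
                        leapfrog_steps=50,
                        seed=seeds["od_mcmc"],
                    ),
                )
            else:
                od = OverdispersionEstimate(mu_od=100.0, sigma_od=20.0, n_posterior=0)
            fit = fit_trajectories(data, od, mcmc=config.mcmc(seeds["fit_mcmc"]))
            fit.summary(config.hpdi_mass).to_csv(
                out / "posterior_summary.tsv", sep="\t", index=False, float_format="%.6g"
            )
            fit.save_draws(out / "posterior_draws.json")
            outliers = flag_outliers(fit, data, cutoff=config.outlier_cutoff)
            outliers.observations.to_csv(out / "outliers.tsv", sep="\t", index=False)
            summary["overdispersion"] = {"mu_od": od.mu_od, "sigma_od": od.sigma_od}
            summary["fixed_rate_proportion"] = outliers.fixed_rate_proportion
            summary["fixed_rate_ci"] = [outliers.ci_low, outliers.ci_high]
            summary["diagnostics"] = fit.diagnostics
            manifest["stages_run"].append("fit")
        except Exception as exc:  # noqa: BLE001
            _fail("fit", exc)

    if config.run_onset and fit is not None:
        try:
            last_ages = (
                data.df.groupby("clone_id")["age_years"].max().to_dict()
            )
            onsets = onset_table(
                fit,
                n_hsc=config.n_hsc,
                g=config.generations_per_year,
                conception=config.conception_onset,
                threshold_vaf=config.detection_threshold_vaf,
                last_ages=last_ages,
                mass=config.hpdi_mass,
            )
            onsets.to_csv(out / "onset.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages_run"].append("onset")
        except Exception as exc:  # noqa: BLE001
            _fail("onset", exc)

    if config.run_phylo and mtree is not None:
        try:
            ttree = scale_tree_to_time(mtree, conception=config.conception_tree)
            clades = detect_clades(ttree)
            clade_rows, traj_rows, decel_rows = [], [], []
            for i, clade in enumerate(clades):
                clade_rows.append(
                    (i, clade.n_tips, clade.clonal_fraction, clade.onset_lower,
                     clade.onset_upper, clade.driver or "")
                )
                if clade.coalescent_times is None or clade.coalescent_times.size < 4:
                    continue
                traj = skyline_neff(clade, ttree, smoothing_epsilon=2.0)
                for t, ne, v, fl in zip(traj.times, traj.neff, traj.variance,
                                        traj.high_variance):
                    traj_rows.append((i, t, ne, v, bool(fl)))
                if (~traj.high_variance).sum() >= 4:
                    bi = fit_biphasic(traj)
                    dec = deceleration_metrics(
                        bi, clade, traj, capacity=config.capacity,
                        sampling_age=ttree.age_at_sampling,
                    )
                    decel_rows.append(
                        (i, bi.early_rate, bi.late_rate, bi.breakpoint,
                         dec.size_ratio, dec.growth_ratio)
                    )
            pd.DataFrame(
                clade_rows,
                columns=["clade", "n_tips", "clonal_fraction", "onset_lower",
                         "onset_upper", "driver"],
            ).to_csv(out / "clades.tsv", sep="\t", index=False, float_format="%.6g")
            pd.DataFrame(
                traj_rows, columns=["clade", "time", "neff", "variance", "high_variance"]
            ).to_csv(out / "neff.tsv", sep="\t", index=False, float_format="%.6g")
            pd.DataFrame(
                decel_rows,
                columns=["clade", "early_rate", "late_rate", "breakpoint",
                         "size_ratio", "growth_ratio"],
            ).to_csv(out / "deceleration.tsv", sep="\t", index=False, float_format="%.6g")
            summary["n_clades"] = len(clades)
            manifest["stages_run"].append("phylo")
        except Exception as exc:  # noqa: BLE001
            _fail("phylo", exc)

    (out / "report.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_yaml(out / "config.yaml")
    return out
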