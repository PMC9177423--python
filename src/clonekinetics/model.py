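"""Hierarchical Bayesian beta-binomial model for serial VAF trajectories.

For individual ``j`` and mutation ``i`` (clone ``c_ij``), variant read counts
at age ``t`` follow

    counts ~ BetaBinomial(depth, alpha(t), beta),
    alpha(t) = beta * q(t) / (1 - q(t)),
    q(t) = ilogit((b_gene + b_site + b_clone) * t + u),

so the expected VAF grows logistically at annual logit-scale rate
``b_total = b_gene + b_site + b_clone``. Gene and recurrent-site effects are
shared across clones (priors N(0, 0.1)); the per-clone "unknown-cause"
effect b_clone ~ N(0, 0.05) absorbs residual growth; ``u`` is the clone's
offset at birth; ``beta`` is the technical overdispersion, given a normal
prior calibrated on replicate sequencing data. Posteriors are sampled by
Hamiltonian Monte Carlo with analytic gradients.

Goodness of fit is scored per observation by posterior-averaged two-sided
beta-binomial tail probabilities with a 2.5% cut-off; clones with no
outlying observation are classified as growing at a fixed exponential rate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv, betaln, expit, gammaln, logit, psi

from clonekinetics._hmc import hmc_chains
from clonekinetics.simulate import LongitudinalDataset, ReplicateSet

__all__ = [
    "MCMCConfig",
    "OverdispersionEstimate",
    "GrowthPosterior",
    "OutlierReport",
    "HPDInterval",
    "estimate_overdispersion",
    "fit_trajectories",
    "flag_outliers",
    "predict_vaf",
    "prediction_mae",
    "hpdi",
]


# ---------------------------------------------------------------------------
# highest posterior density intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.90


def hpdi(samples, mass: float = 0.90) -> HPDInterval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally short windows break to the earliest (lowest) one.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    w = min(int(math.ceil(mass * n)), n)
    widths = s[w - 1:] - s[: n - w + 1]
    i = int(np.argmin(widths))
    return HPDInterval(lower=float(s[i]), upper=float(s[i + w - 1]), mass=mass)


# ---------------------------------------------------------------------------
# configuration and posterior containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """HMC settings. Defaults mirror the analysis protocol: 5,000 iterations
    with the first half discarded as warm-up, 150 leapfrog steps."""

    iterations: int = 5000
    chains: int = 2
    leapfrog_steps: int = 150
    target_accept: float = 0.8
    seed: int = 1
    vaf_ceiling: float = 1.0
    rhat_threshold: float = 1.05

    @property
    def warmup(self) -> int:
        return self.iterations // 2

    @property
    def draws_per_chain(self) -> int:
        return self.iterations - self.warmup

    def reduced(self, iterations: int = 1200, leapfrog_steps: int = 40) -> "MCMCConfig":
        """A cheaper variant for tests and smoke runs."""
        return MCMCConfig(
            iterations=iterations,
            chains=self.chains,
            leapfrog_steps=leapfrog_steps,
            target_accept=self.target_accept,
            seed=self.seed,
            vaf_ceiling=self.vaf_ceiling,
            rhat_threshold=self.rhat_threshold,
        )


@dataclass(frozen=True)
class OverdispersionEstimate:
    """Posterior mean/SD of the beta-binomial concentration parameter."""

    mu_od: float
    sigma_od: float
    n_posterior: int

    def __post_init__(self):
        if self.mu_od <= 0 or self.sigma_od <= 0:
            raise ValueError("mu_od and sigma_od must be positive")


@dataclass
class GrowthPosterior:
    """Posterior draws of the hierarchical growth model.

    Arrays hold pooled post-warm-up draws from all chains; ``clone_gene`` /
    ``clone_site`` give, per clone, the column of its gene/site effect
    (-1 when the clone has none, e.g. single-mutation genes modelled at the
    site level only).
    """

    gene_labels: list[str]
    site_labels: list[str]
    clone_ids: list[str]
    b_gene: np.ndarray  # (n_draws, G)
    b_site: np.ndarray  # (n_draws, S)
    b_clone: np.ndarray  # (n_draws, C)
    u: np.ndarray  # (n_draws, C)
    beta: np.ndarray  # (n_draws,)
    clone_gene: np.ndarray
    clone_site: np.ndarray
    vaf_ceiling: float
    diagnostics: dict = field(default_factory=dict)
    uninformative: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.beta.size

    def _clone_index(self, clone_id: str) -> int:
        try:
            return self.clone_ids.index(clone_id)
        except ValueError:
            raise KeyError(f"unknown clone_id {clone_id!r}") from None

    @property
    def b_total_matrix(self) -> np.ndarray:
        """(n_draws, C): summed gene + site + clone effects, elementwise."""
        out = self.b_clone.copy()
        for c in range(len(self.clone_ids)):
            if self.clone_gene[c] >= 0:
                out[:, c] += self.b_gene[:, self.clone_gene[c]]
            if self.clone_site[c] >= 0:
                out[:, c] += self.b_site[:, self.clone_site[c]]
        return out

    def b_total(self, clone_id: str) -> np.ndarray:
        c = self._clone_index(clone_id)
        out = self.b_clone[:, c].copy()
        if self.clone_gene[c] >= 0:
            out += self.b_gene[:, self.clone_gene[c]]
        if self.clone_site[c] >= 0:
            out += self.b_site[:, self.clone_site[c]]
        return out

    def u_draws(self, clone_id: str) -> np.ndarray:
        return self.u[:, self._clone_index(clone_id)]

    def q_draws(self, clone_id: str, age: float) -> np.ndarray:
        """Posterior draws of the expected VAF at ``age``."""
        eta = self.b_total(clone_id) * age + self.u_draws(clone_id)
        return self.vaf_ceiling * expit(eta)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        rows = []

        def _add(entity, kind, draws):
            iv = hpdi(draws, mass)
            rows.append((entity, kind, float(np.mean(draws)),
                         float(np.median(draws)), iv.lower, iv.upper))

        for gi, lab in enumerate(self.gene_labels):
            _add(lab, "gene", self.b_gene[:, gi])
        for si, lab in enumerate(self.site_labels):
            _add(lab, "site", self.b_site[:, si])
        for ci, cid in enumerate(self.clone_ids):
            _add(cid, "clone", self.b_total(cid))
            _add(cid, "offset", self.u[:, ci])
        _add("beta", "overdispersion", self.beta)
        return pd.DataFrame(
            rows, columns=["entity", "type", "mean", "median", "hpdi_low", "hpdi_high"]
        )

    def save_draws(self, path) -> None:
        payload = {
            "gene_labels": self.gene_labels,
            "site_labels": self.site_labels,
            "clone_ids": self.clone_ids,
            "b_gene": self.b_gene.tolist(),
            "b_site": self.b_site.tolist(),
            "b_clone": self.b_clone.tolist(),
            "u": self.u.tolist(),
            "beta": self.beta.tolist(),
            "clone_gene": self.clone_gene.tolist(),
            "clone_site": self.clone_site.tolist(),
            "vaf_ceiling": self.vaf_ceiling,
            "diagnostics": self.diagnostics,
            "uninformative": self.uninformative,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_draws(cls, path) -> "GrowthPosterior":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_labels=d["gene_labels"],
            site_labels=d["site_labels"],
            clone_ids=d["clone_ids"],
            b_gene=np.asarray(d["b_gene"]),
            b_site=np.asarray(d["b_site"]),
            b_clone=np.asarray(d["b_clone"]),
            u=np.asarray(d["u"]),
            beta=np.asarray(d["beta"]),
            clone_gene=np.asarray(d["clone_gene"]),
            clone_site=np.asarray(d["clone_site"]),
            vaf_ceiling=d["vaf_ceiling"],
            diagnostics=d["diagnostics"],
            uninformative=d["uninformative"],
        )


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

_PRIOR_SD_GENE = 0.1
_PRIOR_SD_SITE = 0.1
_PRIOR_SD_CLONE = 0.05
_PRIOR_MEAN_U = -8.0
_PRIOR_SD_U = 50.0


def assign_effect_labels(df: pd.DataFrame) -> tuple[dict, dict, list[str], list[str]]:
    """Map clones to shared gene/site effect labels.

    Rules: a site gets its own effect when >= 2 individuals carry a missense
    mutation there (a "recurrent site"). A gene whose cohort presence is a
    single recurrent mutation is modelled at the site level only. Genes with
    both truncating and missense mutations get separate effects
    ("GENE:T" / "GENE:M").
    """
    site_indiv = (
        df[(df["consequence"] == "missense") & (df["site"] != "")]
        .groupby(["gene", "site"])["individual_id"]
        .nunique()
    )
    recurrent = {f"{g}:{s}" for (g, s), n in site_indiv.items() if n >= 2}

    clone_rows = df.drop_duplicates("clone_id").set_index("clone_id")
    gene_conseq = df.groupby("gene")["consequence"].agg(lambda x: frozenset(x))
    gene_sites = df.groupby("gene").apply(
        lambda d: set(zip(d["site"], d["consequence"])), include_groups=False
    )

    clone_gene_label: dict[str, str | None] = {}
    clone_site_label: dict[str, str | None] = {}
    for cid, row in clone_rows.iterrows():
        gene, site, conseq = row["gene"], row["site"], row["consequence"]
        site_key = f"{gene}:{site}" if site else ""
        site_lab = site_key if site_key in recurrent and conseq == "missense" else None
        # single-mutation gene: its only recurrent presence is this one site
        single_mutation = (
            site_lab is not None and len(gene_sites[gene]) == 1
        )
        if single_mutation:
            gene_lab = None
        elif len(gene_conseq[gene]) > 1:
            gene_lab = f"{gene}:{'T' if conseq == 'truncating' else 'M'}"
        else:
            gene_lab = gene
        clone_gene_label[cid] = gene_lab
        clone_site_label[cid] = site_lab

    gene_labels = sorted({v for v in clone_gene_label.values() if v is not None})
    site_labels = sorted({v for v in clone_site_label.values() if v is not None})
    return clone_gene_label, clone_site_label, gene_labels, site_labels


def _q_terms(eta: np.ndarray, beta_val: float, ceiling: float):
    """q, 1-q, alpha and d(alpha)/d(eta) for q = ceiling * ilogit(eta)."""
    eta = np.clip(eta, -40.0, 40.0)
    sig = expit(eta)
    q = ceiling * sig
    if ceiling == 1.0:
        one_minus_q = expit(-eta)
    else:
        one_minus_q = 1.0 - q
    one_minus_q = np.maximum(one_minus_q, 1e-15)
    alpha = np.minimum(beta_val * q / one_minus_q, 1e12)  # guard digamma overflow
    dalpha_deta = beta_val * ceiling * sig * (1.0 - sig) / one_minus_q**2
    return q, one_minus_q, alpha, dalpha_deta


def _bb_alpha_grads(k, n, alpha, beta_val):
    """d/d(alpha) and direct d/d(beta) of the beta-binomial log-pmf."""
    common = psi(alpha + beta_val) - psi(n + alpha + beta_val)
    g_alpha = psi(k + alpha) - psi(alpha) + common
    g_beta = psi(n - k + beta_val) - psi(beta_val) + common
    return g_alpha, g_beta


def _bb_loglik(k, n, alpha, beta_val, lgamma_const):
    return lgamma_const + betaln(k + alpha, n - k + beta_val) - betaln(alpha, beta_val)


def fit_trajectories(
    data: LongitudinalDataset,
    od: OverdispersionEstimate,
    mcmc: MCMCConfig | None = None,
) -> GrowthPosterior:
    """Fit the hierarchical growth model to a longitudinal dataset by HMC.

    Returns pooled post-warm-up draws (>= 2,500 at default settings) with
    convergence diagnostics; non-convergence (max R-hat above threshold, or
    divergent transitions) raises a warning, never silently passes.
    """
    if mcmc is None:
        mcmc = MCMCConfig()
    df = data.df.copy()
    df["site"] = df["site"].fillna("").astype(str)
    counts = df.groupby("clone_id")["age_years"].count()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"clones with fewer than 2 timepoints: {bad}")

    clone_gene_label, clone_site_label, gene_labels, site_labels = assign_effect_labels(df)
    clone_ids = sorted(df["clone_id"].unique())
    C, G, S = len(clone_ids), len(gene_labels), len(site_labels)
    clone_pos = {cid: i for i, cid in enumerate(clone_ids)}
    gene_pos = {lab: i for i, lab in enumerate(gene_labels)}
    site_pos = {lab: i for i, lab in enumerate(site_labels)}
    clone_gene = np.array(
        [gene_pos.get(clone_gene_label[cid], -1) for cid in clone_ids], dtype=int
    )
    clone_site = np.array(
        [site_pos.get(clone_site_label[cid], -1) for cid in clone_ids], dtype=int
    )

    t = df["age_years"].to_numpy(float)
    n = df["depth"].to_numpy(float)
    k = df["alt_count"].to_numpy(float)
    ci = df["clone_id"].map(clone_pos).to_numpy(int)
    gi = clone_gene[ci]
    si = clone_site[ci]
    g_mask = gi >= 0
    s_mask = si >= 0
    lgamma_const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    # sample offsets at each clone's mean observation age (v = b*tbar + u):
    # a pure linear reparameterization that removes the near-perfect (b, u)
    # posterior correlation the birth-anchored offset induces
    tbar = np.bincount(ci, weights=t, minlength=C) / np.bincount(ci, minlength=C)
    t_cent = t - tbar[ci]

    ceiling = mcmc.vaf_ceiling
    mu_b, sd_b = float(od.mu_od), float(od.sigma_od)

    # parameter packing: [b_gene, b_site, b_clone, u, r]
    i_bg = slice(0, G)
    i_bs = slice(G, G + S)
    i_bc = slice(G + S, G + S + C)
    i_u = slice(G + S + C, G + S + 2 * C)
    i_r = G + S + 2 * C

    def _b_total_per_clone(bg, bs, bc):
        out = bc.copy()
        has_g = clone_gene >= 0
        has_s = clone_site >= 0
        if G:
            out[has_g] += bg[clone_gene[has_g]]
        if S:
            out[has_s] += bs[clone_site[has_s]]
        return out

    def logp_grad(theta):
        bg = theta[i_bg]
        bs = theta[i_bs]
        bc = theta[i_bc]
        v = theta[i_u]  # offset at each clone's mean observation age
        r = theta[i_r]
        beta_val = math.exp(min(r, 30.0))

        b_clone_tot = _b_total_per_clone(bg, bs, bc)
        eta = b_clone_tot[ci] * t_cent + v[ci]
        q, one_minus_q, alpha, dalpha_deta = _q_terms(eta, beta_val, ceiling)
        lp = float(np.sum(_bb_loglik(k, n, alpha, beta_val, lgamma_const)))
        g_alpha, g_beta_direct = _bb_alpha_grads(k, n, alpha, beta_val)
        geta = g_alpha * dalpha_deta

        # prior acts on the birth-anchored offset u = v - b_total * tbar
        u = v - b_clone_tot * tbar
        du = (u - _PRIOR_MEAN_U) / _PRIOR_SD_U**2

        grad = np.empty_like(theta)
        geta_t = np.bincount(ci, weights=geta * t_cent, minlength=C) + du * tbar
        grad[i_bc] = geta_t - bc / _PRIOR_SD_CLONE**2
        grad[i_u] = np.bincount(ci, weights=geta, minlength=C) - du
        if G:
            grad[i_bg] = (
                np.bincount(clone_gene[clone_gene >= 0], weights=geta_t[clone_gene >= 0],
                            minlength=G)
                - bg / _PRIOR_SD_GENE**2
            )
        if S:
            grad[i_bs] = (
                np.bincount(clone_site[clone_site >= 0], weights=geta_t[clone_site >= 0],
                            minlength=S)
                - bs / _PRIOR_SD_SITE**2
            )
        # beta = exp(r); prior N(mu_od, sd_od) on beta plus log-jacobian r
        dlp_dbeta = float(np.sum(g_alpha * alpha / beta_val + g_beta_direct))
        grad[i_r] = dlp_dbeta * beta_val - (beta_val - mu_b) / sd_b**2 * beta_val + 1.0

        lp += float(
            -0.5 * np.sum(bg**2) / _PRIOR_SD_GENE**2
            - 0.5 * np.sum(bs**2) / _PRIOR_SD_SITE**2
            - 0.5 * np.sum(bc**2) / _PRIOR_SD_CLONE**2
            - 0.5 * np.sum((u - _PRIOR_MEAN_U) ** 2) / _PRIOR_SD_U**2
            - 0.5 * (beta_val - mu_b) ** 2 / sd_b**2
            + r
        )
        return lp, grad

    # initialization: flat growth, offsets from mean VAFs, beta at its prior mean
    theta0 = np.zeros(G + S + 2 * C + 1)
    mean_vaf = df.assign(v=df["alt_count"] / df["depth"]).groupby("clone_id")["v"].mean()
    u0 = logit(np.clip(mean_vaf.reindex(clone_ids).to_numpy() / ceiling, 1e-5, 1 - 1e-5))
    theta0[i_u] = u0
    theta0[i_r] = math.log(mu_b)

    res = hmc_chains(
        logp_grad,
        theta0,
        n_chains=mcmc.chains,
        n_draws=mcmc.draws_per_chain,
        n_warmup=mcmc.warmup,
        leapfrog_steps=mcmc.leapfrog_steps,
        seed=mcmc.seed,
        target_accept=mcmc.target_accept,
    )

    rhat_max = float("nan")
    if mcmc.chains >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(az.convert_to_dataset(res.samples))
            rhat_max = float(np.nanmax(rhat["x"].values))
    diagnostics = {
        "accept_rate": res.accept_rate,
        "n_divergent": int(res.n_divergent),
        "rhat_max": rhat_max,
        "step_size": res.step_size,
        "chains": mcmc.chains,
        "draws": int(res.samples.shape[0] * res.samples.shape[1]),
    }
    if np.isfinite(rhat_max) and rhat_max > mcmc.rhat_threshold:
        warnings.warn(
            f"sampler may not have converged: max R-hat {rhat_max:.3f} "
            f"(threshold {mcmc.rhat_threshold}); diagnostics: {diagnostics}",
            RuntimeWarning,
        )
    if res.n_divergent > 0:
        warnings.warn(
            f"{res.n_divergent} divergent transitions; diagnostics: {diagnostics}",
            RuntimeWarning,
        )

    pooled = res.samples.reshape(-1, theta0.size)
    # convert sampled offsets (at mean observation age) back to birth anchor
    b_tot_draws = pooled[:, i_bc].copy()
    has_g = clone_gene >= 0
    has_s = clone_site >= 0
    if G:
        b_tot_draws[:, has_g] += pooled[:, i_bg][:, clone_gene[has_g]]
    if S:
        b_tot_draws[:, has_s] += pooled[:, i_bs][:, clone_site[has_s]]
    u_draws = pooled[:, i_u] - b_tot_draws * tbar[None, :]
    zero_clones = [
        cid for cid in clone_ids
        if df.loc[df["clone_id"] == cid, "alt_count"].sum() == 0
    ]
    return GrowthPosterior(
        gene_labels=gene_labels,
        site_labels=site_labels,
        clone_ids=clone_ids,
        b_gene=pooled[:, i_bg],
        b_site=pooled[:, i_bs],
        b_clone=pooled[:, i_bc],
        u=u_draws,
        beta=np.exp(pooled[:, i_r]),
        clone_gene=clone_gene,
        clone_site=clone_site,
        vaf_ceiling=ceiling,
        diagnostics=diagnostics,
        uninformative=zero_clones,
    )


# ---------------------------------------------------------------------------
# overdispersion calibration
# ---------------------------------------------------------------------------


def estimate_overdispersion(
    replicates: ReplicateSet,
    mode: str = "triplicate",
    mcmc: MCMCConfig | None = None,
) -> OverdispersionEstimate:
    """Estimate the technical overdispersion ``beta`` from replicate groups.

    Each group's replicates share one latent VAF; counts are beta-binomial
    with concentration ``beta = exp(r)``, ``r`` unconstrained with a flat
    prior. In ``dilution`` mode, groups known to share the same dilution VAF
    also share the latent VAF; ``triplicate`` mode keeps one latent VAF per
    group. Returns the posterior mean and SD of ``beta``.
    """
    if mode not in ("dilution", "triplicate"):
        raise ValueError("mode must be 'dilution' or 'triplicate'")
    if mcmc is None:
        mcmc = MCMCConfig(iterations=3000, leapfrog_steps=50, chains=2)
    df = replicates.df
    nonzero = df.groupby("group_id")["alt_count"].sum()
    keep = set(nonzero[nonzero > 0].index)
    if not keep:
        raise ValueError(
            "all replicate groups have zero variant counts; "
            "overdispersion is not identifiable"
        )
    df = df[df["group_id"].isin(keep)].reset_index(drop=True)
    if df["group_id"].nunique() < 3:
        raise ValueError("need at least 3 informative replicate groups")

    if mode == "dilution" and replicates.true_vafs:
        latent_key = df["group_id"].map(
            lambda gid: f"vaf={replicates.true_vafs.get(gid, gid)}"
        )
    else:
        latent_key = df["group_id"]
    latent_labels = sorted(latent_key.unique())
    pos = {lab: i for i, lab in enumerate(latent_labels)}
    gidx = latent_key.map(pos).to_numpy(int)
    n = df["depth"].to_numpy(float)
    k = df["alt_count"].to_numpy(float)
    lgamma_const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    n_g = len(latent_labels)

    # parameters: z (logit latent VAF per latent group), r = log(beta)
    z_prior_mu, z_prior_sd = -4.0, 3.0

    def logp_grad(theta):
        z = theta[:n_g]
        r = theta[n_g]
        beta_val = math.exp(min(r, 30.0))
        eta = z[gidx]
        q, one_minus_q, alpha, dalpha_deta = _q_terms(eta, beta_val, 1.0)
        lp = float(np.sum(_bb_loglik(k, n, alpha, beta_val, lgamma_const)))
        g_alpha, g_beta_direct = _bb_alpha_grads(k, n, alpha, beta_val)
        geta = g_alpha * dalpha_deta
        grad = np.empty_like(theta)
        grad[:n_g] = np.bincount(gidx, weights=geta, minlength=n_g) - (
            z - z_prior_mu
        ) / z_prior_sd**2
        dlp_dbeta = float(np.sum(g_alpha * alpha / beta_val + g_beta_direct))
        grad[n_g] = dlp_dbeta * beta_val  # flat prior on r
        lp += float(-0.5 * np.sum((z - z_prior_mu) ** 2) / z_prior_sd**2)
        return lp, grad

    theta0 = np.zeros(n_g + 1)
    vbar = (
        df.assign(key=latent_key, v=df["alt_count"] / df["depth"])
        .groupby("key")["v"].mean()
        .reindex(latent_labels)
        .to_numpy()
    )
    theta0[:n_g] = logit(np.clip(vbar, 1e-5, 1 - 1e-5))
    theta0[n_g] = math.log(50.0)

    res = hmc_chains(
        logp_grad,
        theta0,
        n_chains=mcmc.chains,
        n_draws=mcmc.draws_per_chain,
        n_warmup=mcmc.warmup,
        leapfrog_steps=mcmc.leapfrog_steps,
        seed=mcmc.seed,
        target_accept=mcmc.target_accept,
    )
    beta_draws = np.exp(res.samples[:, :, n_g].reshape(-1))
    if beta_draws.size < 1000:
        warnings.warn(
            f"only {beta_draws.size} posterior draws for beta; consider more iterations",
            RuntimeWarning,
        )
    return OverdispersionEstimate(
        mu_od=float(np.mean(beta_draws)),
        sigma_od=float(np.std(beta_draws)),
        n_posterior=int(beta_draws.size),
    )


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Per-observation tail probabilities and per-clone fixed-rate flags."""

    observations: pd.DataFrame
    clones: pd.DataFrame
    fixed_rate_proportion: float
    ci_low: float
    ci_high: float
    cutoff: float = 0.025


def _bb_tails_quadrature(k, n, alpha, beta_val, nodes, weights):
    """Lower/upper beta-binomial tails via Gauss-Legendre quadrature in the
    mixing beta's probability scale: P(X<=k) = E_u[BinCDF(k; n, Q(u))]."""
    p = betaincinv(alpha[:, None], beta_val[:, None], nodes[None, :])
    p = np.clip(p, 1e-300, 1 - 1e-16)

    def bincdf(kk):
        out = np.zeros_like(p)
        valid = kk >= 0
        full = kk >= n
        mid = valid & ~full
        if np.any(mid):
            a = (n - kk)[mid, None]
            b = (kk + 1)[mid, None]
            out[mid] = betainc(a, b, 1.0 - p[mid])
        out[full] = 1.0
        return out @ weights

    lower = bincdf(k)
    upper = 1.0 - bincdf(k - 1)
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def flag_outliers(
    fit: GrowthPosterior,
    data: LongitudinalDataset,
    cutoff: float = 0.025,
    n_posterior_draws: int = 100,
    n_quadrature: int = 48,
) -> OutlierReport:
    """Score every observation by its posterior-averaged two-sided tail
    probability under the fitted beta-binomial; flag tails below ``cutoff``.

    A clone with no flagged observation grows at a fixed exponential rate.
    The cohort-level fixed-rate proportion carries a 90% beta-distributed
    (Jeffreys) confidence interval.
    """
    df = data.df.reset_index(drop=True)
    missing = set(df["clone_id"]) - set(fit.clone_ids)
    if missing:
        raise KeyError(f"clones absent from fit: {sorted(missing)}")

    n = df["depth"].to_numpy(float)
    k = df["alt_count"].to_numpy(float)
    t = df["age_years"].to_numpy(float)
    ci = np.array([fit.clone_ids.index(c) for c in df["clone_id"]])

    draw_idx = np.unique(
        np.linspace(0, fit.n_draws - 1, min(n_posterior_draws, fit.n_draws)).astype(int)
    )
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quadrature)
    nodes = 0.5 * (gl_x + 1.0)
    weights = 0.5 * gl_w

    b_tot = fit.b_total_matrix
    lower_sum = np.zeros(len(df))
    upper_sum = np.zeros(len(df))
    for d in draw_idx:
        eta = b_tot[d, ci] * t + fit.u[d, ci]
        _, _, alpha, _ = _q_terms(eta, float(fit.beta[d]), fit.vaf_ceiling)
        beta_arr = np.full_like(alpha, float(fit.beta[d]))
        lo, up = _bb_tails_quadrature(k, n, alpha, beta_arr, nodes, weights)
        lower_sum += lo
        upper_sum += up
    lower = lower_sum / draw_idx.size
    upper = upper_sum / draw_idx.size
    tail = np.minimum(lower, upper)
    outlier = tail < cutoff

    obs = df.copy()
    obs["tail_lower"] = lower
    obs["tail_upper"] = upper
    obs["tail_probability"] = tail
    obs["outlier"] = outlier

    clones = (
        obs.groupby("clone_id")["outlier"]
        .agg(n_outliers="sum")
        .reset_index()
    )
    clones["fixed_rate"] = clones["n_outliers"] == 0
    n_clones = len(clones)
    n_fixed = int(clones["fixed_rate"].sum())
    from scipy.stats import beta as beta_dist

    ci_low = float(beta_dist.ppf(0.05, n_fixed + 0.5, n_clones - n_fixed + 0.5))
    ci_high = float(beta_dist.ppf(0.95, n_fixed + 0.5, n_clones - n_fixed + 0.5))
    return OutlierReport(
        observations=obs,
        clones=clones,
        fixed_rate_proportion=n_fixed / n_clones,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_vaf(
    fit: GrowthPosterior, clone_id: str, age: float, mass: float = 0.90
) -> tuple[float, HPDInterval]:
    """Posterior-predictive expected VAF of a clone at ``age`` with HPDI."""
    q = fit.q_draws(clone_id, age)
    return float(np.mean(q)), hpdi(q, mass)


def prediction_mae(fit: GrowthPosterior, holdout: LongitudinalDataset | pd.DataFrame) -> float:
    """Mean absolute error, in VAF percentage points, of posterior-mean
    predictions against held-out observations."""
    df = holdout.df if isinstance(holdout, LongitudinalDataset) else holdout
    errs = []
    for _, row in df.iterrows():
        pred, _ = predict_vaf(fit, row["clone_id"], row["age_years"])
        errs.append(abs(pred - row["alt_count"] / row["depth"]))
    return float(np.mean(errs)) * 100.0
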