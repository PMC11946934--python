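"""Bayesian hierarchical model for the non-HIV maternal cause-of-death composition.

Each country ``c`` has a latent composition on the additive log-ratio
(ALR) scale: a vector ``eta_c`` of K−1 log-ratios relative to a fixed
reference cause (``other_direct`` by default), mapped to the K-simplex
by :func:`softmax_complete`. The hierarchy borrows strength across
space::

    eta_c   ~ MVN(mu_region(c), Sigma)        country level
    mu_r    = mu0 + tau * z_r,  z_r ~ N(0, I) region level
    mu0     ~ N(0, s0^2 I)                    global mean

``Sigma`` (parameterised through its Cholesky factor) captures the
correlation between causes that tend to co-occur. Each observation
(data source) sees the country composition through its own noise::

    counts_o ~ Multinomial(n_assigned_o, softmax_complete(eta_c + delta_o))
    delta_o  ~ N(0, (sigma_source(o) * inflate_o)^2 I)

with per-source-type noise SDs constrained to the reliability ordering
confidential_enquiry ≤ CRVS ≤ national_report ≤ subnational_study via
positive increments, and ``inflate_o = sqrt(n_total/n_assigned)``
widening the noise for studies that assigned a cause to only a subset
of their deaths (an alternative that uses only the reduced effective n
is available via ``ModelConfig.partial_assignment``).

Posterior sampling uses the package's Hamiltonian Monte Carlo sampler
on the fully unconstrained, non-centred parametrisation; convergence is
screened with split R-hat and effective sample size (via ``arviz``).
Countries without data are retained in the parameter vector, so their
posterior is exactly the region-level predictive distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from . import hmc
from .causes import CAUSES, DEFAULT_REFERENCE
from .io import Dataset, Observation, SOURCE_TYPES


# --------------------------------------------------------------------------
# link function


def softmax_complete(
    v: np.ndarray,
    reference_cause: str = DEFAULT_REFERENCE,
    causes: Sequence[str] = CAUSES,
) -> np.ndarray:
    """Map K−1 log-ratios to the K-simplex, reference coordinate completed.

    The entry for ``reference_cause`` is ``1 / (1 + sum(exp(v)))``; every
    other cause k gets ``exp(v_k) / (1 + sum(exp(v)))``, with coordinates
    in ``causes`` order.
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("softmax_complete requires finite inputs")
    if v.shape[-1] != len(causes) - 1:
        raise ValueError(f"expected {len(causes) - 1} log-ratios, got {v.shape[-1]}")
    ref = list(causes).index(reference_cause)
    full = np.insert(v, ref, 0.0, axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def alr(
    p: np.ndarray,
    reference_cause: str = DEFAULT_REFERENCE,
    causes: Sequence[str] = CAUSES,
) -> np.ndarray:
    """Additive log-ratio transform, the inverse of :func:`softmax_complete`."""
    p = np.asarray(p, dtype=float)
    ref = list(causes).index(reference_cause)
    logp = np.log(p)
    return np.delete(logp - logp[..., ref : ref + 1], ref, axis=-1)


def log_likelihood(
    linear_predictor: np.ndarray,
    obs: Observation,
    reference_cause: str = DEFAULT_REFERENCE,
    causes: Sequence[str] = CAUSES,
) -> float:
    """Multinomial log-likelihood of one observation's assigned-cause counts.

    ``linear_predictor`` is the observation's ALR vector (country effect
    plus its source-noise vector). Observations with no assigned causes
    carry no likelihood information and contribute 0 (with a warning).
    """
    n = obs.n_assigned
    if n == 0:
        warnings.warn(
            f"observation for {obs.country} has no assigned causes; "
            "likelihood term skipped",
            stacklevel=2,
        )
        return 0.0
    p = softmax_complete(linear_predictor, reference_cause, causes)
    counts = np.asarray(obs.counts, dtype=float)
    coef = gammaln(n + 1) - gammaln(counts + 1).sum()
    return float(coef + (counts * np.log(p)).sum())


# --------------------------------------------------------------------------
# configuration and results


@dataclass
class ModelConfig:
    reference_cause: str = DEFAULT_REFERENCE
    prior_mu0_scale: float = 2.0
    prior_tau_scale: float = 1.0  # half-normal on the region-level SD
    prior_chol_diag_loc: float = float(np.log(0.3))  # lognormal on Cholesky diagonal
    prior_chol_diag_scale: float = 1.0
    prior_chol_offdiag_scale: float = 0.3
    prior_source_increment_loc: float = float(np.log(0.1))
    prior_source_increment_scale: float = 1.0
    partial_assignment: str = "sqrt_inflation"  # or "effective_n_only"
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    leapfrog_steps: int = 64
    target_accept: float = 0.85
    seed: int = 0
    max_rhat: float = 1.05
    min_ess: float = 400.0

    def validate(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")
        if self.max_rhat <= 0 or self.min_ess <= 0:
            raise ValueError("convergence thresholds must be positive")
        if self.partial_assignment not in ("sqrt_inflation", "effective_n_only"):
            raise ValueError(f"unknown partial_assignment rule {self.partial_assignment!r}")


@dataclass
class PosteriorSamples:
    """Posterior draws of all model parameters plus derived compositions."""

    causes: tuple[str, ...]
    reference_cause: str
    countries: list[str]
    regions: list[str]
    country_region_idx: np.ndarray  # (C,) region index per country
    mu0: np.ndarray  # (chains, draws, K-1)
    tau: np.ndarray  # (chains, draws)
    mu_region: np.ndarray  # (chains, draws, R, K-1)
    eta: np.ndarray  # (chains, draws, C, K-1)
    p: np.ndarray  # (chains, draws, C, K)
    chol: np.ndarray  # (chains, draws, K-1, K-1) Cholesky of Sigma
    sigma_source: np.ndarray  # (chains, draws, n_source_types)
    source_types: tuple[str, ...] = SOURCE_TYPES
    diagnostics: dict = field(default_factory=dict)
    converged: bool = False
    chain_stats: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.p.shape[0]

    @property
    def n_draws(self) -> int:
        return self.p.shape[1]

    @property
    def n_total_draws(self) -> int:
        return self.n_chains * self.n_draws

    @property
    def Sigma(self) -> np.ndarray:
        return self.chol @ np.swapaxes(self.chol, -1, -2)

    def p_flat(self) -> np.ndarray:
        """All composition draws, shape (chains*draws, C, K)."""
        return self.p.reshape(-1, len(self.countries), len(self.causes))

    def p_draws(self, country: str) -> np.ndarray:
        """Composition draws for one country, shape (chains*draws, K)."""
        return self.p_flat()[:, self.countries.index(country), :]

    def validate_draws(self) -> None:
        pf = self.p_flat()
        if not np.allclose(pf.sum(axis=-1), 1.0, atol=1e-10):
            raise AssertionError("composition draws must sum to 1")
        if (pf <= 0).any() or (pf >= 1).any():
            raise AssertionError("composition draws must lie strictly inside (0, 1)")
        if (np.diff(self.sigma_source, axis=-1) < 0).any():
            raise AssertionError("source SD draws must respect the reliability ordering")


def region_predictive_draws(
    ps: PosteriorSamples, region: str, seed: int = 0
) -> np.ndarray:
    """Fresh composition draws from the region-level predictive, shape (S, K).

    For each posterior draw of (mu_region, Sigma), draws one new country
    effect — the distribution a data-free country in that region follows.
    """
    r = ps.regions.index(region)
    S = ps.n_total_draws
    d = len(ps.causes) - 1
    mu_r = ps.mu_region.reshape(S, len(ps.regions), d)[:, r, :]
    L = ps.chol.reshape(S, d, d)
    z = np.random.default_rng(seed).standard_normal((S, d))
    eta = mu_r + np.einsum("sij,sj->si", L, z)
    return softmax_complete(eta, ps.reference_cause, ps.causes)


# --------------------------------------------------------------------------
# the log-posterior (unconstrained, non-centred) and its gradient


class _Layout:
    """Slices of the flat unconstrained parameter vector."""

    def __init__(self, d: int, R: int, C: int, O: int, n_src: int):
        self.d, self.R, self.C, self.O, self.n_src = d, R, C, O, n_src
        self.nb = d * (d - 1) // 2
        sizes = {
            "mu0": d,
            "log_tau": 1,
            "z": R * d,
            "a": d,
            "b": self.nb,
            "u": C * d,
            "c_src": n_src,
            "w": O * d,
        }
        self.slices = {}
        off = 0
        for k, s in sizes.items():
            self.slices[k] = slice(off, off + s)
            off += s
        self.dim = off
        self.tril = np.tril_indices(d, k=-1)


def _build_logp_grad(
    counts: np.ndarray,  # (O, K_cat) assigned-cause counts
    n_total: np.ndarray,  # (O,) all deaths in the study (for inflation)
    country_idx: np.ndarray,  # (O,)
    src_idx: np.ndarray,  # (O,)
    region_of_country: np.ndarray,  # (C,)
    n_regions: int,
    ref_idx: int,
    cfg: ModelConfig,
):
    K_cat = counts.shape[1]
    d = K_cat - 1
    O = counts.shape[0]
    C = len(region_of_country)
    lay = _Layout(d, n_regions, C, O, len(SOURCE_TYPES))

    nonref = [k for k in range(K_cat) if k != ref_idx]
    counts_nr = counts[:, nonref].astype(float)
    n_obs = counts.sum(axis=1).astype(float)
    if cfg.partial_assignment == "sqrt_inflation":
        inflate = np.sqrt(n_total / np.maximum(n_obs, 1.0))
    else:
        inflate = np.ones(O)
    diag_idx = np.arange(d)
    s0sq = cfg.prior_mu0_scale**2
    tau_sc_sq = cfg.prior_tau_scale**2
    a_loc, a_sc = cfg.prior_chol_diag_loc, cfg.prior_chol_diag_scale
    b_sc = cfg.prior_chol_offdiag_scale
    c_loc, c_sc = cfg.prior_source_increment_loc, cfg.prior_source_increment_scale

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # extreme trajectories overflow exp(); they yield -inf/nan log density
        # and are rejected by the sampler, so silence the transient warnings
        with np.errstate(over="ignore", invalid="ignore"):
            return _logp_grad_inner(theta)

    def _logp_grad_inner(theta: np.ndarray) -> tuple[float, np.ndarray]:
        s = lay.slices
        mu0 = theta[s["mu0"]]
        log_tau = theta[s["log_tau"]][0]
        Z = theta[s["z"]].reshape(lay.R, d)
        a = theta[s["a"]]
        b = theta[s["b"]]
        U = theta[s["u"]].reshape(C, d)
        c_src = theta[s["c_src"]]
        W = theta[s["w"]].reshape(O, d) if O else np.zeros((0, d))

        tau = np.exp(log_tau)
        L = np.zeros((d, d))
        L[diag_idx, diag_idx] = np.exp(a)
        L[lay.tril] = b
        sig_inc = np.exp(c_src)
        sigma_src = np.cumsum(sig_inc)

        mu_r = mu0[None, :] + tau * Z  # (R, d)
        eps_c = U @ L.T  # (C, d)
        eta = mu_r[region_of_country] + eps_c  # (C, d)

        logp = 0.0
        grad = np.zeros(lay.dim)

        if O:
            s_obs = sigma_src[src_idx] * inflate  # (O,)
            V = eta[country_idx] + s_obs[:, None] * W  # (O, d)
            m = np.maximum(V.max(axis=1), 0.0)
            logZ = m + np.log(np.exp(-m) + np.exp(V - m[:, None]).sum(axis=1))
            logp += float((counts_nr * V).sum() - (n_obs * logZ).sum())
            p_nr = np.exp(V - logZ[:, None])
            gV = counts_nr - n_obs[:, None] * p_nr  # (O, d)

            # delta_o = s_obs * W_o
            grad[s["w"]] = (gV * s_obs[:, None] - W).ravel()
            logp += float(-0.5 * (W * W).sum())

            # source SDs through the ordered cumulative-sum transform
            gs_obs = (gV * W).sum(axis=1) * inflate  # d loglik / d sigma_{src(o)}
            T = np.zeros(lay.n_src)
            np.add.at(T, src_idx, gs_obs)
            grad[s["c_src"]] = sig_inc * np.cumsum(T[::-1])[::-1]

            G = np.zeros((C, d))
            np.add.at(G, country_idx, gV)
        else:
            G = np.zeros((C, d))

        # country level
        grad[s["u"]] = (G @ L - U).ravel()
        logp += float(-0.5 * (U * U).sum())
        gL = G.T @ U  # (d, d); lower-triangular part is used
        grad[s["a"]] = np.diag(gL) * np.exp(a) - (a - a_loc) / a_sc**2
        logp += float(-0.5 * (((a - a_loc) / a_sc) ** 2).sum())
        grad[s["b"]] = gL[lay.tril] - b / b_sc**2
        logp += float(-0.5 * ((b / b_sc) ** 2).sum())

        # region level
        H = np.zeros((lay.R, d))
        np.add.at(H, region_of_country, G)
        grad[s["z"]] = (tau * H - Z).ravel()
        logp += float(-0.5 * (Z * Z).sum())
        grad[s["log_tau"]] = tau * float((Z * H).sum()) - tau**2 / tau_sc_sq + 1.0
        logp += float(-0.5 * tau**2 / tau_sc_sq + log_tau)

        # global mean
        grad[s["mu0"]] = H.sum(axis=0) - mu0 / s0sq
        logp += float(-0.5 * (mu0 * mu0).sum() / s0sq)

        # prior on source increments
        grad[s["c_src"]] = grad[s["c_src"]] - (c_src - c_loc) / c_sc**2
        logp += float(-0.5 * (((c_src - c_loc) / c_sc) ** 2).sum())
        return logp, grad

    return logp_grad, lay


def _fit_counts(
    counts: np.ndarray,
    n_total: np.ndarray,
    country_idx: np.ndarray,
    src_idx: np.ndarray,
    region_of_country: np.ndarray,
    n_regions: int,
    labels: tuple[str, ...],
    reference: str,
    cfg: ModelConfig,
) -> dict:
    """Shared sampling core for the main model and the subgroup models."""
    K_cat = len(labels)
    d = K_cat - 1
    ref_idx = list(labels).index(reference)
    C = len(region_of_country)
    logp_grad, lay = _build_logp_grad(
        counts, n_total, country_idx, src_idx, region_of_country, n_regions, ref_idx, cfg
    )

    init_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    x0s = []
    for _ in range(cfg.chains):
        x0 = 0.1 * init_rng.standard_normal(lay.dim)
        x0[lay.slices["a"]] += cfg.prior_chol_diag_loc
        x0[lay.slices["c_src"]] += cfg.prior_source_increment_loc
        x0s.append(x0)
    draws, stats = hmc.sample(
        logp_grad,
        x0s,
        n_warmup=cfg.warmup,
        n_draws=cfg.draws,
        seed=cfg.seed + 1,
        target_accept=cfg.target_accept,
        leapfrog_steps=cfg.leapfrog_steps,
    )

    ch, dr, _ = draws.shape
    s = lay.slices
    flat = draws.reshape(ch * dr, -1)
    mu0 = flat[:, s["mu0"]]
    tau = np.exp(flat[:, s["log_tau"]][:, 0])
    Z = flat[:, s["z"]].reshape(-1, n_regions, d)
    a = flat[:, s["a"]]
    b = flat[:, s["b"]]
    U = flat[:, s["u"]].reshape(-1, C, d)
    sigma_src = np.cumsum(np.exp(flat[:, s["c_src"]]), axis=1)
    S = flat.shape[0]
    L = np.zeros((S, d, d))
    L[:, np.arange(d), np.arange(d)] = np.exp(a)
    L[:, lay.tril[0], lay.tril[1]] = b
    mu_r = mu0[:, None, :] + tau[:, None, None] * Z
    eta = mu_r[:, region_of_country, :] + np.einsum("sij,scj->sci", L, U)
    p = softmax_complete(eta, reference, labels)
    return {
        "mu0": mu0.reshape(ch, dr, d),
        "tau": tau.reshape(ch, dr),
        "mu_region": mu_r.reshape(ch, dr, n_regions, d),
        "eta": eta.reshape(ch, dr, C, d),
        "p": p.reshape(ch, dr, C, K_cat),
        "chol": L.reshape(ch, dr, d, d),
        "sigma_source": sigma_src.reshape(ch, dr, len(SOURCE_TYPES)),
        "chain_stats": stats,
    }


# --------------------------------------------------------------------------
# public fitting interface


def _dataset_arrays(ds: Dataset):
    countries = ds.countries
    regions = ds.regions
    c_index = {c: i for i, c in enumerate(countries)}
    r_index = {r: i for i, r in enumerate(regions)}
    region_of_country = np.array([r_index[ds.region_map[c]] for c in countries])
    usable = []
    for o in ds.observations:
        if o.n_assigned == 0:
            warnings.warn(
                f"observation for {o.country} ({o.source_type}, "
                f"{o.period_start}-{o.period_end}) has no assigned causes; "
                "excluded from the likelihood",
                stacklevel=3,
            )
            continue
        usable.append(o)
    counts = np.array([o.counts for o in usable], dtype=np.int64).reshape(
        len(usable), len(CAUSES)
    )
    n_total = np.array([o.n_total for o in usable], dtype=float)
    country_idx = np.array([c_index[o.country] for o in usable], dtype=int)
    src_idx = np.array([SOURCE_TYPES.index(o.source_type) for o in usable], dtype=int)
    return countries, regions, region_of_country, counts, n_total, country_idx, src_idx


def fit(ds: Dataset, cfg: Optional[ModelConfig] = None) -> PosteriorSamples:
    """Sample the posterior of the hierarchical composition model.

    Returns draws for every country in the estimation target set,
    including countries with no observations (whose posterior is the
    region-level predictive). The result is flagged ``converged=False``
    (with a warning) if any monitored quantity fails the R-hat or ESS
    thresholds; it is never silently discarded.
    """
    cfg = cfg or ModelConfig()
    cfg.validate()
    countries, regions, region_of_country, counts, n_total, country_idx, src_idx = (
        _dataset_arrays(ds)
    )
    if counts.shape[0] == 0:
        raise ValueError("cannot fit: no observation carries assigned-cause counts")
    res = _fit_counts(
        counts,
        n_total,
        country_idx,
        src_idx,
        region_of_country,
        len(regions),
        CAUSES,
        cfg.reference_cause,
        cfg,
    )
    ps = PosteriorSamples(
        causes=CAUSES,
        reference_cause=cfg.reference_cause,
        countries=countries,
        regions=regions,
        country_region_idx=region_of_country,
        mu0=res["mu0"],
        tau=res["tau"],
        mu_region=res["mu_region"],
        eta=res["eta"],
        p=res["p"],
        chol=res["chol"],
        sigma_source=res["sigma_source"],
        chain_stats=res["chain_stats"],
    )
    ps.validate_draws()
    ps.diagnostics = diagnostics(ps, max_rhat=cfg.max_rhat, min_ess=cfg.min_ess)
    ps.converged = ps.diagnostics["converged"]
    if not ps.converged:
        warnings.warn(
            "posterior flagged non-converged: "
            + "; ".join(ps.diagnostics["flagged"][:5]),
            stacklevel=2,
        )
    return ps


def diagnostics(
    ps: PosteriorSamples, max_rhat: float = 1.05, min_ess: float = 400.0
) -> dict:
    """Split R-hat, bulk ESS and divergence counts per parameter block."""
    import arviz as az

    if ps.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    post = {
        "mu0": ps.mu0,
        "tau": ps.tau,
        "sigma_source": ps.sigma_source,
        "eta": ps.eta,
    }
    idata = az.from_dict(posterior=post)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    report: dict = {"blocks": {}, "flagged": []}
    for name in post:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = float(np.nanmax(np.asarray(rhat[name])))
            e = float(np.nanmin(np.asarray(ess[name])))
        if np.isnan(r):  # constant parameter block (degenerate but not mixing failure)
            r = 1.0
        if np.isnan(e):
            e = float("inf")
        report["blocks"][name] = {"rhat_max": r, "ess_min": e}
        if r > max_rhat:
            report["flagged"].append(f"{name}: R-hat {r:.3f} > {max_rhat}")
        if e < min_ess:
            report["flagged"].append(f"{name}: ESS {e:.0f} < {min_ess:.0f}")
    report["rhat_max"] = max(b["rhat_max"] for b in report["blocks"].values())
    report["ess_min"] = min(b["ess_min"] for b in report["blocks"].values())
    report["n_divergent"] = int(sum(st.n_divergent for st in ps.chain_stats))
    # isolated energy-threshold rejections are benign for static HMC; flag
    # only a persistent divergence rate
    if report["n_divergent"] > 0.005 * ps.n_total_draws:
        report["flagged"].append(f"{report['n_divergent']} divergent transitions")
    report["converged"] = not report["flagged"]
    return report
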