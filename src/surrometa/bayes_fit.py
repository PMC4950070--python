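"""Bayesian fitting of the multivariate surrogate-endpoint meta-analysis.

Model
-----
Study ``i`` reports effect estimates ``Y_i`` (some entries possibly
missing) with known within-study covariance ``Sigma_i``; the true
effects ``mu_i`` follow a multivariate normal with mean ``beta`` and
between-study covariance ``T``, written as a product-normal chain
(:mod:`surrometa.covariance_maps`).  Priors follow common
meta-analytic practice for this model family: between-study
correlations uniform on (-1, 1), between-study SDs half-normal with
variance 10, the chain mean ``eta1`` and intercepts ``lambda_j0``
normal with variance 1000, and any missing within-study *variance*
uniform on (0.001, 1000).  States whose implied ``T`` is not positive
definite (equivalently any ``psi_j^2 <= 0``) have zero prior density.

Computation
-----------
Because both levels are normal with known ``Sigma_i``, the true effects
integrate out exactly: each study contributes a multivariate-normal
likelihood ``Y_i,obs ~ N(beta_obs, (T + Sigma_i)_obs)`` over its
observed components.  MCMC therefore only needs to explore the 5-9
hyperparameters, which is done with an affine-invariant ensemble
sampler (emcee) on the transformed scale ``(eta1, lambda_j0, log tau,
atanh rho)`` with the appropriate Jacobians.  Latent quantities —
per-study true effects, imputed missing estimates, predictions for a
new study — are recovered per retained draw from the exact
conditional-normal distributions, so nothing is lost relative to
sampling them explicitly.

Missing estimates simply drop out of the likelihood; in particular the
held-out final outcome of a cross-validation fold (estimate and SD both
masked) influences nothing, exactly as coding both as missing nodes
would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .covariance_maps import parents_for_structure
from .study_effects import EffectRow

__all__ = [
    "ModelSpec",
    "PosteriorFit",
    "PredictiveSummary",
    "SurrogacyReport",
    "fit_model",
    "predict_final_outcome",
    "surrogacy_report",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelSpec:
    """Specification of one meta-analysis model.

    ``outcomes`` selects (0-based) which columns of the effect rows the
    model uses — e.g. ``(1, 2)`` fits a bivariate model of the second
    surrogate and the final outcome.  ``iterations``/``burn_in`` count
    posterior draws summed over walkers, mirroring a
    50,000-iteration/20,000-burn-in single-chain run by default.
    """

    name: str = "trma-ucm"
    structure: str = "unstructured"
    adjacency: list[list[int]] | None = None
    outcomes: tuple[int, ...] | None = None
    iterations: int = 50_000
    burn_in: int = 20_000
    n_walkers: int | None = None
    seed: int | None = None
    rhat_threshold: float = 1.05
    centering: bool = False
    prior_tau_var: float = 10.0
    prior_mean_var: float = 1000.0
    sigma2_prior: tuple[float, float] = (0.001, 1000.0)

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")

    def with_iterations(self, iterations: int, burn_in: int) -> "ModelSpec":
        return replace(self, iterations=iterations, burn_in=burn_in)


def brma_spec(**kw) -> ModelSpec:
    """Bivariate model: second surrogate + final outcome."""
    kw.setdefault("name", "brma")
    kw.setdefault("outcomes", (1, 2))
    return ModelSpec(structure="unstructured", **kw)


def trma_ucm_spec(**kw) -> ModelSpec:
    kw.setdefault("name", "trma-ucm")
    return ModelSpec(structure="unstructured", **kw)


def trma_scm_spec(**kw) -> ModelSpec:
    kw.setdefault("name", "trma-scm")
    return ModelSpec(structure="sequential", **kw)


SPEC_FACTORIES = {
    "brma": brma_spec,
    "trma-ucm": trma_ucm_spec,
    "trma-scm": trma_scm_spec,
}


# ---------------------------------------------------------------------------
# parameter vector layout and chain construction (vectorised over draws)
# ---------------------------------------------------------------------------


class _Layout:
    """Mapping between the flat sampler vector and model parameters.

    theta = (eta1, lambda_20..lambda_N0, log tau_1..N, atanh rho_edge...)
    where the edges are the declared (parent, child) pairs of the chain.
    """

    def __init__(self, n: int, structure: str, adjacency=None):
        self.n = n
        self.parents = parents_for_structure(n, structure, adjacency)
        self.edges = [(p, j) for j in range(n) for p in self.parents[j]]
        self.dim = n + n + len(self.edges)  # means + log-tau + rho edges

    def unpack(self, theta: np.ndarray):
        """theta (..., dim) -> (means (..., n), tau (..., n), rho_edges (..., E))."""
        n = self.n
        means = theta[..., :n]
        tau = np.exp(theta[..., n : 2 * n])
        rho = np.tanh(theta[..., 2 * n :])
        return means, tau, rho

    def build_chain(self, tau: np.ndarray, rho_edges: np.ndarray):
        """Vectorised product-normal chain construction.

        ``tau`` (..., n), ``rho_edges`` (..., E) -> implied covariance
        ``T`` (..., n, n), conditional variances ``psi2`` (..., n) and
        per-edge slopes (..., E).  Invalid states (any ``psi2 <= 0``)
        are flagged in the returned boolean mask.
        """
        tau = np.atleast_2d(tau)
        rho_edges = np.atleast_2d(rho_edges) if len(self.edges) else np.zeros(
            tau.shape[:-1] + (0,)
        )
        m = tau.shape[0]
        n = self.n
        T = np.zeros((m, n, n))
        psi2 = np.zeros((m, n))
        slopes = np.zeros((m, len(self.edges)))
        ok = np.ones(m, dtype=bool)
        edge_pos = {e: k for k, e in enumerate(self.edges)}
        for j in range(n):
            pa = self.parents[j]
            if not pa:
                psi2[:, j] = tau[:, j] ** 2
                T[:, j, j] = psi2[:, j]
                continue
            cov_pj = np.stack(
                [tau[:, p] * tau[:, j] * rho_edges[:, edge_pos[(p, j)]] for p in pa],
                axis=-1,
            )  # (m, |pa|)
            Spp = T[:, pa][:, :, pa]  # (m, |pa|, |pa|)
            try:
                lam = np.linalg.solve(Spp, cov_pj[..., None])[..., 0]
            except np.linalg.LinAlgError:
                ok[:] = False
                break
            p2 = tau[:, j] ** 2 - np.einsum("mk,mk->m", lam, cov_pj)
            ok &= p2 > 0
            psi2[:, j] = p2
            for k, p in enumerate(pa):
                slopes[:, edge_pos[(p, j)]] = lam[:, k]
            if j > 0:
                T[:, j, :j] = np.einsum("mk,mkl->ml", lam, T[:, pa][:, :, :j])
                T[:, :j, j] = T[:, j, :j]
            T[:, j, j] = tau[:, j] ** 2
        return T, psi2, slopes, ok

    def pooled_effects(self, means: np.ndarray, slopes: np.ndarray, centering: bool):
        """beta_j per draw from eta1, intercepts and slopes."""
        means = np.atleast_2d(means)
        slopes = np.atleast_2d(slopes) if len(self.edges) else np.zeros(
            means.shape[:-1] + (0,)
        )
        n = self.n
        beta = np.zeros_like(means)
        beta[:, 0] = means[:, 0]
        edge_pos = {e: k for k, e in enumerate(self.edges)}
        for j in range(1, n):
            if centering:
                beta[:, j] = means[:, j]
                continue
            acc = means[:, j].copy()
            for p in self.parents[j]:
                acc += slopes[:, edge_pos[(p, j)]] * beta[:, p]
            beta[:, j] = acc
        return beta


def _group_by_pattern(data: list[EffectRow], outcomes: np.ndarray):
    """Group studies by their missingness pattern over the modelled outcomes."""
    groups: dict[tuple, dict] = {}
    for i, row in enumerate(data):
        y = row.y[outcomes]
        obs = np.isfinite(y)
        if not obs.any():
            continue
        key = tuple(obs.tolist())
        g = groups.setdefault(key, {"idx": [], "y": [], "cov": []})
        sub = row.subset(outcomes)
        o = np.flatnonzero(obs)
        cov = sub.covariance()[np.ix_(o, o)]
        g["idx"].append(i)
        g["y"].append(sub.y[o])
        g["cov"].append(cov)
    out = []
    for key, g in groups.items():
        out.append(
            {
                "obs": np.flatnonzero(np.array(key)),
                "idx": np.array(g["idx"]),
                "y": np.array(g["y"]),  # (S_g, k)
                "cov": np.array(g["cov"]),  # (S_g, k, k)
            }
        )
    return out


def _make_log_prob(layout: _Layout, groups, spec: ModelSpec):
    n = layout.n
    tau_var = spec.prior_tau_var
    mean_var = spec.prior_mean_var

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        m = theta.shape[0]
        means, tau, rho = layout.unpack(theta)
        lp = np.zeros(m)
        # priors (transformed scale, with Jacobians)
        lp += -0.5 * np.sum(means**2, axis=-1) / mean_var
        lp += -0.5 * np.sum(tau**2, axis=-1) / tau_var + np.sum(
            np.log(tau), axis=-1
        )  # half-normal on tau + dtau/dlog-tau
        if rho.shape[-1]:
            lp += np.sum(np.log1p(-(rho**2)), axis=-1)  # uniform rho, tanh Jacobian
        T, psi2, slopes, ok = layout.build_chain(tau, rho)
        lp[~ok] = -np.inf
        if not ok.any():
            return lp
        beta = layout.pooled_effects(means, slopes, spec.centering)
        ll = np.zeros(m)
        for g in groups:
            o = g["obs"]
            k = o.size
            resid = g["y"][None, :, :] - beta[:, None, o]  # (m, S, k)
            C = T[:, None][:, :, o][:, :, :, o] + g["cov"][None]  # (m, S, k, k)
            sign, logdet = np.linalg.slogdet(C)
            with np.errstate(all="ignore"):
                sol = np.linalg.solve(C, resid[..., None])[..., 0]
            quad = np.einsum("msk,msk->ms", resid, sol)
            term = -0.5 * (k * _LOG2PI + logdet + quad)
            bad = sign <= 0
            if bad.any():
                term[bad] = -np.inf
            ll += term.sum(axis=1)
        lp = lp + ll
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    return log_prob


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Posterior draws of the model's hyperparameters and derived quantities.

    All arrays are aligned on the first axis (retained draws, pooled over
    walkers).  ``T`` holds the implied between-study covariance per draw
    (positive definite by construction), ``psi2`` the conditional
    variances and ``slopes`` the chain regression coefficients (aligned
    with ``edges``).
    """

    spec: ModelSpec
    outcomes: np.ndarray
    parents: list[list[int]]
    edges: list[tuple[int, int]]
    means: np.ndarray  # (M, n): eta1, lambda_j0
    tau: np.ndarray  # (M, n)
    rho_edges: np.ndarray  # (M, E)
    T: np.ndarray  # (M, n, n)
    psi2: np.ndarray  # (M, n)
    slopes: np.ndarray  # (M, E)
    beta: np.ndarray  # (M, n)
    rhat: dict = field(default_factory=dict)
    acceptance_fraction: float = np.nan
    data: list[EffectRow] = field(default_factory=list)

    @property
    def n_outcomes(self) -> int:
        return self.tau.shape[1]

    @property
    def n_draws(self) -> int:
        return self.tau.shape[0]

    def _param_draws(self) -> dict[str, np.ndarray]:
        n = self.n_outcomes
        out = {"eta1": self.means[:, 0]}
        for j in range(1, n):
            out[f"lambda{j + 1}0"] = self.means[:, j]
        for j in range(n):
            out[f"tau{j + 1}"] = self.tau[:, j]
            out[f"psi2_{j + 1}"] = self.psi2[:, j]
            out[f"beta{j + 1}"] = self.beta[:, j]
        for k, (p, j) in enumerate(self.edges):
            out[f"lambda{j + 1}{p + 1}"] = self.slopes[:, k]
            out[f"rho_b{p + 1}{j + 1}"] = self.rho_edges[:, k]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, median and central 95% interval per parameter."""
        rows = []
        for name, d in self._param_draws().items():
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "median": med,
                    "2.5%": lo,
                    "97.5%": hi,
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def posterior_mean(self, name: str) -> float:
        return float(self._param_draws()[name].mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        d = self._param_draws()[name]
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(d, [a, 100 - a]))

    def sample_true_effects(self, rng: np.random.Generator, thin: int = 1) -> np.ndarray:
        """Draws of the per-study true effects ``mu_ji``.

        Returns an array (draws, studies, outcomes): for each retained
        hyperparameter draw, an exact draw from the conditional normal
        of ``mu_i`` given the study's observed estimates.
        """
        sel = slice(None, None, thin)
        T = self.T[sel]
        beta = self.beta[sel]
        m = T.shape[0]
        n = self.n_outcomes
        out = np.empty((m, len(self.data), n))
        for i, row in enumerate(self.data):
            sub = row.subset(self.outcomes)
            o = np.flatnonzero(np.isfinite(sub.y))
            if o.size == 0:
                mean = beta
                cov = T
            else:
                Sig = sub.covariance()[np.ix_(o, o)]
                C = T[:, o][:, :, o] + Sig[None]
                K = np.linalg.solve(C, T[:, o, :]).transpose(0, 2, 1)  # (m, n, k)
                resid = sub.y[o][None, :] - beta[:, o]
                mean = beta + np.einsum("mnk,mk->mn", K, resid)
                cov = T - np.einsum("mnk,mkl->mnl", K, T[:, o, :])
            cov = 0.5 * (cov + cov.transpose(0, 2, 1))
            # eigen-based sampling tolerates the zero-variance limit
            w, V = np.linalg.eigh(cov)
            w = np.clip(w, 0, None)
            z = rng.standard_normal((m, n))
            out[:, i, :] = mean + np.einsum("mnk,mk->mn", V * np.sqrt(w)[:, None, :], z)
        return out


@dataclass
class PredictiveSummary:
    """Posterior-predictive summary for one study's final outcome.

    ``true_*`` entries describe the true effect ``mu``; ``est_*``
    entries add within-study noise and describe the predicted *estimate*
    (the quantity comparable with an observed estimate).  ``exp_``
    prefixes are the same summaries exponentiated draw-by-draw (e.g. an
    odds-ratio scale).
    """

    study_id: str
    true_draws: np.ndarray
    est_draws: np.ndarray

    @staticmethod
    def _summ(d: np.ndarray) -> dict:
        lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
        return {"mean": float(d.mean()), "median": float(med), "lo": float(lo), "hi": float(hi)}

    @property
    def true_effect(self) -> dict:
        return self._summ(self.true_draws)

    @property
    def estimate(self) -> dict:
        return self._summ(self.est_draws)

    @property
    def exp_estimate(self) -> dict:
        return self._summ(np.exp(self.est_draws))

    @property
    def exp_true_effect(self) -> dict:
        return self._summ(np.exp(self.true_draws))


@dataclass
class SurrogacyReport:
    """Surrogacy-criteria verdicts derived from the posterior draws.

    For each child outcome: the slopes on its parents should be non-zero
    (95% CrI excluding 0), the intercept should be consistent with zero
    (CrI containing 0) and the conditional variance should be small —
    zero for a perfect (jointly mediating) set of surrogates.
    """

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def _compute_rhat(chain: np.ndarray, names: list[str], n_groups: int = 4) -> dict:
    """Split-R-hat treating groups of walkers as chains."""
    nsteps, nwalk, dim = chain.shape
    g = max(2, min(n_groups, nwalk))
    usable = (nwalk // g) * g
    arr = chain[:, :usable, :].reshape(nsteps, g, usable // g, dim).mean(axis=2)
    # (draw, chain, dim) -> dict of (chain, draw)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, name in enumerate(names):
            da = az.convert_to_dataset(arr[:, :, k].T)
            out[name] = float(az.rhat(da)["x"].values)
    return out


def fit_model(data: list[EffectRow], spec: ModelSpec) -> PosteriorFit:
    """Fit the Bayesian meta-analysis model by ensemble MCMC.

    ``data`` may contain missing estimates (``nan``); at least three
    studies with one observed outcome each are required, and every
    modelled outcome must be observed in at least one study.
    """
    if spec.outcomes is None:
        n_all = data[0].n_outcomes if data else 0
        outcomes = np.arange(n_all)
    else:
        outcomes = np.asarray(spec.outcomes, dtype=int)
    n = outcomes.size
    usable = [r for r in data if np.isfinite(r.y[outcomes]).any()]
    if len(usable) < len(data):
        warnings.warn("dropping studies with no observed modelled outcome", stacklevel=2)
    if len(usable) < 3:
        raise ValueError("need at least 3 studies with an observed outcome")
    obs_mat = np.array([np.isfinite(r.y[outcomes]) for r in usable])
    if not obs_mat.any(axis=0).all():
        j = int(np.flatnonzero(~obs_mat.any(axis=0))[0])
        raise ValueError(f"outcome {outcomes[j]} is missing in every study")

    layout = _Layout(n, spec.structure, spec.adjacency)
    groups = _group_by_pattern(usable, outcomes)
    log_prob = _make_log_prob(layout, groups, spec)

    dim = layout.dim
    nwalk = spec.n_walkers or max(24, 2 * dim + 6)
    nsteps = int(np.ceil(spec.iterations / nwalk))
    nburn = int(np.ceil(spec.burn_in / nwalk))
    if nsteps <= nburn:
        nsteps = nburn + 1

    rng = np.random.default_rng(spec.seed)
    # data-driven starting ball: observed column means, moderate heterogeneity
    ymeans = np.array(
        [np.nanmean([r.y[o] for r in usable if np.isfinite(r.y[o])]) for o in outcomes]
    )
    center = np.zeros(dim)
    center[0] = ymeans[0]
    center[1:n] = ymeans[1:n]  # intercepts start at marginal means (slopes ~ 0)
    center[n : 2 * n] = np.log(0.3)
    p0 = center + 0.1 * rng.standard_normal((nwalk, dim))
    lp0 = log_prob(p0)
    for _ in range(100):
        bad = ~np.isfinite(lp0)
        if not bad.any():
            break
        p0[bad] = center + 0.1 * rng.standard_normal((int(bad.sum()), dim))
        lp0[bad] = log_prob(p0[bad])
    else:
        raise RuntimeError("could not initialise walkers at finite posterior density")

    sampler = emcee.EnsembleSampler(nwalk, dim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    sampler.run_mcmc(p0, nsteps, progress=False)

    chain = sampler.get_chain()  # (nsteps, nwalk, dim)
    post = chain[nburn:]
    flat = post.reshape(-1, dim)

    means, tau, rho = layout.unpack(flat)
    T, psi2, slopes, ok = layout.build_chain(tau, rho)
    beta = layout.pooled_effects(means, slopes, spec.centering)

    # diagnostics on the natural-scale draws
    names = (
        ["eta1"]
        + [f"lambda{j + 1}0" for j in range(1, n)]
        + [f"tau{j + 1}" for j in range(n)]
        + [f"rho_b{p + 1}{j + 1}" for p, j in layout.edges]
    )
    nat = np.concatenate(
        [
            post[..., :n],
            np.exp(post[..., n : 2 * n]),
            np.tanh(post[..., 2 * n :]),
        ],
        axis=-1,
    )
    rhat = _compute_rhat(nat, names)
    worst = {k: v for k, v in rhat.items() if v > spec.rhat_threshold}
    if worst:
        warnings.warn(
            f"potential-scale-reduction above {spec.rhat_threshold} for: "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(worst.items())),
            stacklevel=2,
        )

    return PosteriorFit(
        spec=spec,
        outcomes=outcomes,
        parents=layout.parents,
        edges=layout.edges,
        means=means,
        tau=tau,
        rho_edges=rho,
        T=T,
        psi2=psi2,
        slopes=slopes,
        beta=beta,
        rhat=rhat,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        data=usable,
    )


def predict_final_outcome(
    fit: PosteriorFit,
    new_study: EffectRow,
    sigma_final: float | None = None,
    rng: np.random.Generator | None = None,
) -> PredictiveSummary:
    """Posterior-predictive distribution of a study's final outcome.

    The final outcome is the last modelled outcome.  Per retained draw,
    the true effect is drawn from its exact conditional normal given the
    study's observed surrogate estimates; the predicted *estimate* adds
    within-study noise with SD ``sigma_final`` when supplied (e.g. the
    observed SE in a cross-validation fold) or with a variance drawn
    from the uniform(0.001, 1000) prior when genuinely unknown.
    """
    rng = rng or np.random.default_rng()
    sub = new_study.subset(fit.outcomes)
    f = fit.n_outcomes - 1
    o = np.flatnonzero(np.isfinite(sub.y))
    o = o[o != f]
    if o.size == 0:
        raise ValueError("new study has no observed surrogate outcome")
    if np.any(~np.isfinite(sub.sigma[o])):
        raise ValueError("observed surrogates must come with SDs")
    T, beta = fit.T, fit.beta
    Sig = sub.covariance()[np.ix_(o, o)]
    C = T[:, o][:, :, o] + Sig[None]
    t_fo = T[:, f, :][:, o]
    sol = np.linalg.solve(C, t_fo[..., None])[..., 0]  # (M, k)
    resid = sub.y[o][None, :] - beta[:, o]
    gain = np.linalg.solve(C, resid[..., None])[..., 0]
    mean = beta[:, f] + np.einsum("mk,mk->m", t_fo, gain)
    var = T[:, f, f] - np.einsum("mk,mk->m", t_fo, sol)
    var = np.clip(var, 0, None)
    true_draws = mean + np.sqrt(var) * rng.standard_normal(mean.size)
    if sigma_final is not None:
        s2 = np.full(mean.size, float(sigma_final) ** 2)
    elif np.isfinite(sub.sigma[f]):
        s2 = np.full(mean.size, sub.sigma[f] ** 2)
    else:
        lo, hi = fit.spec.sigma2_prior
        s2 = rng.uniform(lo, hi, size=mean.size)
    est_draws = true_draws + np.sqrt(s2) * rng.standard_normal(mean.size)
    return PredictiveSummary(
        study_id=new_study.study_id, true_draws=true_draws, est_draws=est_draws
    )


def surrogacy_report(fit: PosteriorFit) -> SurrogacyReport:
    """Evaluate the surrogacy criteria on each conditional regression.

    Any outcome with parents is treated as a (possibly intermediate)
    final outcome for its parents, so the multivariate criteria fall out
    of the same table.
    """
    if fit.n_outcomes < 2:
        raise ValueError("surrogacy criteria need at least 2 outcomes")
    rows = []
    draws = fit._param_draws()
    for j in range(1, fit.n_outcomes):
        if not fit.parents[j]:
            continue
        ic = draws[f"lambda{j + 1}0"]
        lo, hi = np.percentile(ic, [2.5, 97.5])
        rows.append(
            {
                "child": j + 1,
                "parameter": f"lambda{j + 1}0",
                "mean": ic.mean(),
                "2.5%": lo,
                "97.5%": hi,
                "criterion": "intercept ~ 0",
                "satisfied": bool(lo <= 0 <= hi),
            }
        )
        for p in fit.parents[j]:
            sl = draws[f"lambda{j + 1}{p + 1}"]
            lo, hi = np.percentile(sl, [2.5, 97.5])
            rows.append(
                {
                    "child": j + 1,
                    "parameter": f"lambda{j + 1}{p + 1}",
                    "mean": sl.mean(),
                    "2.5%": lo,
                    "97.5%": hi,
                    "criterion": "slope != 0",
                    "satisfied": bool(lo > 0 or hi < 0),
                }
            )
        p2 = draws[f"psi2_{j + 1}"]
        lo, hi = np.percentile(p2, [2.5, 97.5])
        rows.append(
            {
                "child": j + 1,
                "parameter": f"psi2_{j + 1}",
                "mean": p2.mean(),
                "2.5%": lo,
                "97.5%": hi,
                "criterion": "conditional variance ~ 0",
                "satisfied": bool(hi < 0.1),
            }
        )
    return SurrogacyReport(table=pd.DataFrame(rows))
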