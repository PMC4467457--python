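"""Bayesian inference of ddG energy matrices from PBM probe z-scores.

The observation model follows the occupancy (BEEML-style) framework: a probe
containing a site with total energy E (RT units, anchored so the canonical
site scores 0) is occupied with probability

    occ = 1 / (1 + exp(E - mu)),

where mu = ln([TF]/Kd_optimal) is the chemical potential absorbing protein
concentration and optimal-site affinity.  Occupancy maps linearly onto the
observed z-score scale, z_pred = a + (b - a) * occ, with a and b the lower
and upper scaling asymptotes.  Observed z-scores are modelled as Normal
around z_pred with noise scale sigma (half-Cauchy(5) prior); non-anchored
ddG entries carry an exponential prior with mean 10 RT, shifted so a small
negative floor (default -2 RT) remains representable — anchoring is the
canonical-code base, and NN repeats can genuinely prefer A, so fitted
entries below the anchor must not be forbidden.  mu, a and b get uniform
priors.

Two fitting paths are provided:

* ``method="mcmc"`` — affine-invariant ensemble sampling (emcee), run as
  ``n_chains`` independent ensembles whose flattened draws are treated as
  chains for the split Gelman-Rubin statistic (converged when all R-hat
  < 1.05).  Posterior means and central 95% credible intervals are reported.
* ``method="map"`` — a fast path: L-BFGS-B maximum a posteriori fit with a
  Laplace (inverse-Hessian) approximation for the credible intervals,
  clearly labelled in the result's ``method`` tag.

``fit_scaling`` refits only (mu, a, b) by Levenberg-Marquardt for a fixed,
known energy matrix, which is how predicted PWMs are evaluated against
probe intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .energy_model import BASES, BASE_INDEX, EnergyMatrix, canonical_anchors
from .tale_core import TALEProtein, canonical_target_site

__all__ = [
    "BindingModelParams",
    "FitConfig",
    "PosteriorEM",
    "predict_occupancy",
    "predict_zscores",
    "fit_ddg_posterior",
    "fit_scaling",
    "check_convergence",
    "split_rhat",
]


@dataclass
class BindingModelParams:
    """Chemical potential and linear scaling terms of the occupancy model."""

    mu: float
    a: float
    b: float


@dataclass
class FitConfig:
    n_chains: int = 4
    burn_in: int = 500
    samples: int = 2000
    prior_mean: float = 10.0
    init_nonpref: float = 3.0
    init_mu: float = -1.0
    rhat_threshold: float = 1.05
    seed: int = 0
    method: str = "mcmc"  # "mcmc" | "map"
    ddg_floor: float = 2.0  # entries bounded below by -ddg_floor
    truncate_at_zero: bool = False  # forbid negative ddG entirely
    sigma_prior_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains >= 2 required for convergence checking")
        for name in ("burn_in", "samples", "prior_mean", "init_nonpref", "rhat_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.method not in ("mcmc", "map"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def floor(self) -> float:
        return 0.0 if self.truncate_at_zero else self.ddg_floor


@dataclass
class PosteriorEM:
    mean_em: EnergyMatrix
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    rhat: dict[str, float | None]
    params: dict[str, dict[str, float]]
    converged: bool
    method: str
    param_names: list[str] = field(default_factory=list)


# ---- forward model ------------------------------------------------------

def predict_occupancy(em: EnergyMatrix, mu: float, site) -> float:
    """Fractional occupancy of a site: logistic in (E - mu)."""
    from .energy_model import site_ddg

    e = site_ddg(em, site)
    return float(_sigmoid(mu - e))


def predict_zscores(em: EnergyMatrix, params: BindingModelParams, sites) -> np.ndarray:
    """z_pred = a + (b - a) * occupancy for each site."""
    from .energy_model import site_ddg

    e = np.array([site_ddg(em, s) for s in sites])
    occ = _sigmoid(params.mu - e)
    return params.a + (params.b - params.a) * occ


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# ---- design matrix ------------------------------------------------------

def _free_param_names(protein: TALEProtein) -> tuple[list[str], np.ndarray, list[tuple[int, int]]]:
    """Names and (position, base) layout of the non-anchored ddG parameters."""
    anchors = canonical_anchors(protein)
    layout = []
    names = []
    for j, anc in enumerate(anchors):
        for bi in range(4):
            if bi == anc:
                continue
            layout.append((j, bi))
            names.append(f"ddg[{j}:{BASES[bi]}]")
    return names, anchors, layout


def _design_matrix(sites: list[str], layout: list[tuple[int, int]], length: int) -> np.ndarray:
    """Indicator matrix M: E_i = M_i @ ddg_free (anchored bases contribute 0)."""
    index = {(j, bi): k for k, (j, bi) in enumerate(layout)}
    M = np.zeros((len(sites), len(layout)))
    for i, s in enumerate(sites):
        if len(s) != length:
            raise ValueError(f"site {s!r} length != {length}")
        for j, base in enumerate(s):
            k = index.get((j, BASE_INDEX[base]))
            if k is not None:
                M[i, k] = 1.0
    return M


def _theta_to_em(ddg_free: np.ndarray, layout, anchors, length) -> EnergyMatrix:
    values = np.zeros((length, 4))
    for k, (j, bi) in enumerate(layout):
        values[j, bi] = ddg_free[k]
    return EnergyMatrix(values=values, anchors=anchors)


# ---- log posterior ------------------------------------------------------

class _Posterior:
    """Negative log posterior and gradient in theta = [ddg_free, mu, a, b, log_sigma]."""

    def __init__(self, M: np.ndarray, z: np.ndarray, config: FitConfig):
        self.M = M
        self.z = z
        self.cfg = config
        self.nd = M.shape[1]
        self.ndim = self.nd + 4
        zr = float(z.max() - z.min()) or 1.0
        self.bounds = (
            [(-config.floor, 30.0)] * self.nd
            + [(-30.0, 30.0)]
            + [(z.min() - 5 * zr, z.max() + 5 * zr)] * 2
            + [(np.log(1e-4), np.log(1e3))]
        )

    def unpack(self, theta):
        return theta[..., : self.nd], theta[..., self.nd], theta[..., self.nd + 1], theta[..., self.nd + 2], theta[..., self.nd + 3]

    def neg_log_post(self, theta: np.ndarray) -> float:
        d, mu, a, b, s = self.unpack(theta)
        sigma = np.exp(s)
        e = self.M @ d
        g = _sigmoid(mu - e)
        r = self.z - (a + (b - a) * g)
        n = self.z.size
        nll = n * s + 0.5 * (r @ r) / sigma**2
        # shifted-exponential prior on ddG; half-Cauchy(scale) on sigma incl. Jacobian
        prior = (d + self.cfg.floor).sum() / self.cfg.prior_mean
        prior += np.log1p((sigma / self.cfg.sigma_prior_scale) ** 2) - s
        return float(nll + prior)

    def grad(self, theta: np.ndarray) -> np.ndarray:
        d, mu, a, b, s = self.unpack(theta)
        sigma = np.exp(s)
        e = self.M @ d
        g = _sigmoid(mu - e)
        zp = a + (b - a) * g
        r = self.z - zp
        inv = 1.0 / sigma**2
        gg = g * (1.0 - g)
        out = np.empty(self.ndim)
        out[: self.nd] = inv * (b - a) * (self.M.T @ (r * gg)) + 1.0 / self.cfg.prior_mean
        out[self.nd] = -inv * (b - a) * np.sum(r * gg)
        out[self.nd + 1] = -inv * np.sum(r * (1.0 - g))
        out[self.nd + 2] = -inv * np.sum(r * g)
        sc = self.cfg.sigma_prior_scale
        out[self.nd + 3] = self.z.size - inv * (r @ r) + 2 * sigma**2 / (sc**2 + sigma**2) - 1.0
        return out

    def log_prob_vec(self, thetas: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for an ensemble of walkers (-inf off bounds)."""
        thetas = np.atleast_2d(thetas)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        ok = np.all((thetas >= lo) & (thetas <= hi), axis=1)
        out = np.full(thetas.shape[0], -np.inf)
        if not ok.any():
            return out
        t = thetas[ok]
        d, mu, a, b, s = self.unpack(t)
        sigma = np.exp(s)
        e = d @ self.M.T
        g = _sigmoid(mu[:, None] - e)
        r = self.z[None, :] - (a[:, None] + (b - a)[:, None] * g)
        n = self.z.size
        nll = n * s + 0.5 * np.sum(r * r, axis=1) / sigma**2
        prior = (d + self.cfg.floor).sum(axis=1) / self.cfg.prior_mean
        prior += np.log1p((sigma / self.cfg.sigma_prior_scale) ** 2) - s
        out[ok] = -(nll + prior)
        return out

    def initial_point(self) -> np.ndarray:
        theta = np.empty(self.ndim)
        theta[: self.nd] = self.cfg.init_nonpref
        theta[self.nd] = self.cfg.init_mu
        theta[self.nd + 1] = float(self.z.min())
        theta[self.nd + 2] = float(self.z.max())
        theta[self.nd + 3] = np.log(max(0.05 * (self.z.max() - self.z.min()), 1e-3))
        return theta

    def map_fit(self) -> np.ndarray:
        # the posterior is multimodal in mu (occupancy saturates at both
        # ends), so restart over a grid of chemical potentials and keep the
        # best mode; each restart is cheap with the analytic gradient.  A
        # too-small initial sigma makes the first gradient so steep that the
        # line search overshoots into the saturated plateau, so the grid also
        # spans a tempered (larger) noise scale.
        best = None
        z_range = float(self.z.max() - self.z.min())
        for mu0 in (-3.0, self.cfg.init_mu, 1.0, 3.0, 6.0):
            for sigma_frac in (0.05, 0.25):
                x0 = self.initial_point()
                x0[self.nd] = mu0
                x0[-1] = np.log(max(sigma_frac * z_range, 1e-3))
                res = optimize.minimize(
                    self.neg_log_post,
                    x0,
                    jac=self.grad,
                    method="L-BFGS-B",
                    bounds=self.bounds,
                    options={"maxiter": 2000},
                )
                if best is None or res.fun < best.fun:
                    best = res
        return best.x

    def hessian(self, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        """Central finite differences of the analytic gradient."""
        H = np.zeros((self.ndim, self.ndim))
        for i in range(self.ndim):
            step = eps * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += step
            tm[i] -= step
            H[:, i] = (self.grad(tp) - self.grad(tm)) / (2 * step)
        return 0.5 * (H + H.T)


# ---- public fitting API -------------------------------------------------

def fit_ddg_posterior(
    protein: TALEProtein,
    variant_zscores: dict[str, float],
    config: FitConfig | None = None,
) -> PosteriorEM:
    """Infer the posterior energy matrix of ``protein`` from variant z-scores.

    ``variant_zscores`` maps each measured site-variant sequence (same length
    as the protein's canonical site) to its probe z-score.  The probe set
    must cover every single substitution of the canonical site; a position
    with no variant coverage is reported by index.
    """
    config = config or FitConfig()
    names, anchors, layout = _free_param_names(protein)
    length = protein.site_length
    sites = list(variant_zscores)
    z = np.array([variant_zscores[s] for s in sites], dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    M = _design_matrix(sites, layout, length)
    covered = M.sum(axis=0) > 0
    if not covered.all():
        by_pos = {}
        for k, (j, bi) in enumerate(layout):
            if not covered[k]:
                by_pos.setdefault(j, []).append(BASES[bi])
        msg = "; ".join(f"position {j}: bases {''.join(bs)}" for j, bs in sorted(by_pos.items()))
        raise ValueError(f"no variant coverage for {msg}")

    post = _Posterior(M, z, config)
    all_names = names + ["mu", "a", "b", "sigma"]

    if config.method == "map":
        theta = post.map_fit()
        H = post.hessian(theta)
        converged = True
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            if np.any(var <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            var = np.abs(np.diag(cov))
            converged = False
        sd = np.sqrt(var)
        mean, lower, upper = theta, theta - 1.96 * sd, theta + 1.96 * sd
        rhat: dict[str, float | None] = {n: None for n in all_names}
        method = "map-laplace"
        chains = None
    else:
        chains = _run_mcmc(post, config)
        flat = chains.reshape(-1, post.ndim)
        mean = flat.mean(axis=0)
        lower = np.percentile(flat, 2.5, axis=0)
        upper = np.percentile(flat, 97.5, axis=0)
        rhat_vals = check_convergence(chains)
        rhat = dict(zip(all_names, [None if np.isnan(v) else float(v) for v in rhat_vals]))
        finite = [v for v in rhat.values() if v is not None]
        converged = bool(finite) and max(finite) < config.rhat_threshold
        method = "mcmc-emcee"

    mean_em = _theta_to_em(mean[: post.nd], layout, anchors, length)
    ci_lo = _theta_to_em(lower[: post.nd], layout, anchors, length).values
    ci_hi = _theta_to_em(upper[: post.nd], layout, anchors, length).values
    params = {}
    for k, name in enumerate(("mu", "a", "b", "sigma")):
        i = post.nd + k
        val = np.exp(mean[i]) if name == "sigma" else mean[i]
        lo = np.exp(lower[i]) if name == "sigma" else lower[i]
        hi = np.exp(upper[i]) if name == "sigma" else upper[i]
        params[name] = {"mean": float(val), "ci_lower": float(lo), "ci_upper": float(hi)}
    return PosteriorEM(
        mean_em=mean_em,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        rhat=rhat,
        params=params,
        converged=converged,
        method=method,
        param_names=all_names,
    )


def _run_mcmc(post: _Posterior, config: FitConfig) -> np.ndarray:
    """Run n_chains independent ensembles; returns (n_chains, draws, ndim)."""
    import emcee

    ndim = post.ndim
    nwalkers = max(2 * ndim + 2, 48)
    if nwalkers % 2:
        nwalkers += 1
    center = post.map_fit()
    lo = np.array([b[0] for b in post.bounds])
    hi = np.array([b[1] for b in post.bounds])
    keep_steps = max(config.samples // nwalkers, 20)
    chains = []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        p0 = center[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, post.log_prob_vec, vectorize=True
        )
        sampler._random = np.random.RandomState(int(child.generate_state(1)[0]) % (2**32 - 1))
        state = sampler.run_mcmc(p0, config.burn_in, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, keep_steps, progress=False)
        chains.append(sampler.get_chain().reshape(-1, ndim))  # (steps*walkers, ndim)
    return np.array(chains)


# ---- convergence --------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split Gelman-Rubin statistic for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, then the
    classic between/within variance ratio is computed.  Returns NaN when all
    draws are identical (the statistic is undefined for constant chains).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("need >= 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    if np.ptp(split) == 0:
        return float("nan")
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W == 0:
        return float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def check_convergence(chains: np.ndarray) -> np.ndarray:
    """Split R-hat per parameter for draws shaped (n_chains, n_draws, n_params).

    Constant parameters yield NaN entries (reported, never propagated into
    the convergence verdict)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    return np.array([split_rhat(chains[:, :, k]) for k in range(chains.shape[2])])


# ---- scaling-only refit -------------------------------------------------

def fit_scaling(
    em: EnergyMatrix,
    sites: list,
    zscores: np.ndarray,
    init: BindingModelParams | None = None,
) -> tuple[BindingModelParams, float]:
    """Levenberg-Marquardt refit of (mu, a, b) with the energy matrix fixed.

    Initialization follows the standard scheme a = min z, b = max z,
    mu = -1.  Returns fitted parameters and the coefficient of determination
    R^2 between predicted and observed z-scores.
    """
    from .energy_model import site_ddg

    z = np.asarray(zscores, dtype=float)
    e = np.array([site_ddg(em, s) for s in sites])
    if len(np.unique(np.round(e, 12))) < 4:
        raise ValueError("need >= 4 probes with distinct site energies")
    if init is None:
        init = BindingModelParams(mu=-1.0, a=float(z.min()), b=float(z.max()))

    def resid(p):
        mu, a, b = p
        return z - (a + (b - a) * _sigmoid(mu - e))

    res = optimize.least_squares(
        resid, x0=[init.mu, init.a, init.b], method="lm", max_nfev=10000
    )
    if not res.success:
        raise RuntimeError(f"scaling fit did not converge: {res.message}")
    mu, a, b = res.x
    pred = a + (b - a) * _sigmoid(mu - e)
    ss_res = float(np.sum((z - pred) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BindingModelParams(mu=float(mu), a=float(a), b=float(b)), r2
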