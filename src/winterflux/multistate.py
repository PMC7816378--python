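"""Bayesian nine-state multistate capture-recapture model.

Geese move weekly among eight wintering regions with region-specific
survival (phi), transition (psi, row-stochastic), and detection (p)
probabilities; dead is absorbing and always unobserved.  Capture
histories carry observed codes 1-8 (seen in region) or 9 (not observed),
conditioned on each individual's first observation.

Transitions are parameterised with a per-row multinomial logit relative
to "stay", so the seven off-diagonal probabilities always sum to less
than one and fidelity is the complement.  The posterior is sampled with
a block-wise adaptive random-walk Metropolis sampler (one block per
transition row, one each for survival and detection) on the forward-
algorithm likelihood; convergence is assessed with the Gelman-Rubin
potential scale reduction factor at the 1.10 criterion.

Survival and detection cannot be separated from transmitter failure and
are estimated only as nuisance parameters; reports label them so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import (
    N_REGIONS,
    build_matrices,
    forward_loglik_one,
    log_posterior,
    theta_to_matrices,
)

NOT_OBSERVED = 9
RHAT_CRITERION = 1.10
PRIOR_FLOOR = 0.001  # posterior mean at or below this "returns the prior"

_BLOCKS = [list(range(7 * r, 7 * r + 7)) for r in range(8)] + [
    list(range(56, 64)),
    list(range(64, 72)),
]


@dataclass
class ModelSpec:
    """Fixed parameter values (used for likelihood evaluation and tests)."""

    psi: np.ndarray
    phi: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, float)
        self.phi = np.atleast_1d(np.asarray(self.phi, float))
        self.p = np.atleast_1d(np.asarray(self.p, float))
        if self.phi.size == 1:
            self.phi = np.full(N_REGIONS, self.phi[0])
        if self.p.size == 1:
            self.p = np.full(N_REGIONS, self.p[0])
        if self.psi.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("psi must be 8x8 (embed smaller toys in 8 states)")
        if not np.allclose(self.psi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("psi rows must sum to 1")

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return build_matrices(self.psi, self.phi, self.p)


def expand_spec(psi, phi, p) -> ModelSpec:
    """Embed a toy model with fewer regions into the 8-region state space.

    Unused regions become absorbing with detection matching ``p`` so they
    never enter the likelihood of histories that avoid them.
    """
    psi = np.asarray(psi, float)
    k = psi.shape[0]
    full = np.eye(N_REGIONS)
    full[:k, :k] = psi
    phi_full = np.full(N_REGIONS, 1.0)
    phi_full[:k] = np.atleast_1d(phi) if np.size(phi) > 1 else phi
    p_full = np.full(N_REGIONS, 1.0)
    p_full[:k] = np.atleast_1d(p) if np.size(p) > 1 else p
    return ModelSpec(psi=full, phi=phi_full, p=p_full)


def loglik_forward(history, spec: ModelSpec) -> float:
    """Forward-algorithm log-probability of one capture history.

    The history is conditioned on its first observed (non-9) state; a
    single-observation history therefore has log-probability 0.
    """
    y = np.asarray(history, dtype=np.int64)
    if np.any((y < 1) | (y > 9)):
        raise ValueError("history codes must be in 1..9")
    obs_idx = np.nonzero(y != NOT_OBSERVED)[0]
    if obs_idx.size == 0:
        return 0.0
    Omega, Theta = spec.matrices()
    return float(forward_loglik_one(y, int(obs_idx[0]), Omega, Theta))


def observed_transition_support(Y: np.ndarray) -> np.ndarray:
    """Counts of directly observed week-to-week transitions (8x8).

    Counts pairs of consecutive weeks where both states are observed;
    this is the support used to decide which transition estimates are
    interpretable versus prior-returned.
    """
    Y = np.asarray(Y, dtype=int)
    counts = np.zeros((N_REGIONS, N_REGIONS), dtype=int)
    a = Y[:, :-1]
    b = Y[:, 1:]
    mask = (a >= 1) & (a <= 8) & (b >= 1) & (b <= 8)
    for r, s in zip(a[mask] - 1, b[mask] - 1):
        counts[r, s] += 1
    return counts


def gelman_rubin(chains: np.ndarray) -> float | np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m_chains, n_draws) or (m, n, k) for k
    parameters at once.  Constant identical chains return 1 by
    convention (0/0 guarded).  Requires >= 2 chains and >= 10 draws.
    """
    x = np.asarray(chains, float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[..., None]
    m, n = x.shape[0], x.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W <= 0, 1.0, rhat)
    return float(rhat[0]) if squeeze else rhat


@dataclass
class DerivedRates:
    """Posterior fidelity / cumulative immigration / emigration per region."""

    fidelity_mean: np.ndarray
    fidelity_ci: np.ndarray  # (8, 2)
    cum_immigration_mean: np.ndarray
    cum_immigration_ci: np.ndarray
    cum_emigration_mean: np.ndarray
    cum_emigration_ci: np.ndarray


@dataclass
class MultistateResults:
    """Posterior draws and summaries from :meth:`MultistateModel.fit`."""

    psi_draws: np.ndarray  # (chains, draws, 8, 8)
    phi_draws: np.ndarray  # (chains, draws, 8)
    p_draws: np.ndarray  # (chains, draws, 8)
    support: np.ndarray  # (8, 8) observed transition counts
    acceptance: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        flat = self.psi_flat
        assert np.allclose(flat.sum(axis=2), 1.0, atol=1e-9), "psi draws not row-stochastic"
        self.rhat_psi = gelman_rubin(
            self.psi_draws.reshape(*self.psi_draws.shape[:2], 64)
        ).reshape(8, 8)
        self.rhat_phi = np.asarray(gelman_rubin(self.phi_draws))
        self.rhat_p = np.asarray(gelman_rubin(self.p_draws))
        self.psi_mean = flat.mean(axis=0)
        self.psi_ci = np.percentile(flat, [2.5, 97.5], axis=0)
        self.returned_prior = (self.support == 0) & (self.psi_mean <= PRIOR_FLOOR)
        np.fill_diagonal(self.returned_prior, False)
        interpreted = self.interpreted_mask()
        self.converged = bool(np.all(self.rhat_psi[interpreted] <= RHAT_CRITERION))

    @property
    def psi_flat(self) -> np.ndarray:
        """Pooled post-burn-in draws, shape (n_total, 8, 8)."""
        return self.psi_draws.reshape(-1, 8, 8)

    def interpreted_mask(self) -> np.ndarray:
        """Transition entries with observed support (the interpretable set)."""
        mask = self.support > 0
        np.fill_diagonal(mask, True)  # fidelity always interpreted
        return mask

    def max_rhat_interpreted(self) -> float:
        return float(self.rhat_psi[self.interpreted_mask()].max())

    def derive_rates(self) -> DerivedRates:
        """Fidelity, cumulative immigration and emigration, per draw.

        fidelity + cum_emigration = 1 holds exactly per draw because the
        rows are stochastic by construction.
        """
        flat = self.psi_flat
        diag = np.einsum("drr->dr", flat)
        emi = 1.0 - diag
        imm = flat.sum(axis=1) - diag  # column sums minus own diagonal
        pct = lambda x: np.percentile(x, [2.5, 97.5], axis=0).T
        return DerivedRates(
            fidelity_mean=diag.mean(axis=0),
            fidelity_ci=pct(diag),
            cum_immigration_mean=imm.mean(axis=0),
            cum_immigration_ci=pct(imm),
            cum_emigration_mean=emi.mean(axis=0),
            cum_emigration_ci=pct(emi),
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(8):
            for s in range(8):
                rows.append(
                    {
                        "parameter": f"psi[{r + 1},{s + 1}]",
                        "mean": self.psi_mean[r, s],
                        "lcl": self.psi_ci[0, r, s],
                        "ucl": self.psi_ci[1, r, s],
                        "rhat": self.rhat_psi[r, s],
                        "converged": self.rhat_psi[r, s] <= RHAT_CRITERION,
                        "returned_prior": bool(self.returned_prior[r, s]),
                        "n_support": int(self.support[r, s]),
                        "role": "transition",
                    }
                )
        phi_flat = self.phi_draws.reshape(-1, 8)
        p_flat = self.p_draws.reshape(-1, 8)
        for name, draws, rhat in (
            ("phi", phi_flat, self.rhat_phi),
            ("p", p_flat, self.rhat_p),
        ):
            ci = np.percentile(draws, [2.5, 97.5], axis=0)
            for r in range(8):
                rows.append(
                    {
                        "parameter": f"{name}[{r + 1}]",
                        "mean": draws[:, r].mean(),
                        "lcl": ci[0, r],
                        "ucl": ci[1, r],
                        "rhat": rhat[r],
                        "converged": rhat[r] <= RHAT_CRITERION,
                        "returned_prior": False,
                        "n_support": -1,
                        "role": "nuisance",
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        rates = self.derive_rates()
        lines = [
            "Multistate capture-recapture posterior summary",
            f"  chains={self.config.get('chains')}, iterations={self.config.get('iterations')},"
            f" burn_in={self.config.get('burn_in')}, thin={self.config.get('thin')}",
            f"  all interpreted transitions converged (R-hat <= {RHAT_CRITERION}): {self.converged}"
            f" (max R-hat = {self.max_rhat_interpreted():.3f})",
            "  weekly fidelity (posterior mean [95% CrI]):",
        ]
        from .regions import REGION_NAMES

        for r in range(8):
            lines.append(
                f"    {REGION_NAMES[r + 1]:>24s}: {rates.fidelity_mean[r]:.2f}"
                f" [{rates.fidelity_ci[r, 0]:.2f}, {rates.fidelity_ci[r, 1]:.2f}]"
            )
        n_rp = int(self.returned_prior.sum())
        lines.append(f"  transitions returning the prior (never observed): {n_rp}")
        lines.append("  survival/detection estimated as nuisance only (not interpreted)")
        return "\n".join(lines)


class MultistateModel:
    """Fit the weekly multistate model to a capture-history matrix.

    Parameters
    ----------
    histories : array-like or DataFrame
        (n_individuals, n_weeks) observed codes 1-9; a frame with
        week_* columns (as written by ``weekly_collapse``) also works.
    psi_prior_sd : float
        SD of the vague normal prior on transition logits.
    uniform_prob_prior : bool
        If True, survival/detection get Uniform(0, 1) priors on the
        probability scale instead of Normal(0, 1) on the logit scale.
    """

    def __init__(
        self,
        histories,
        psi_prior_sd: float = 10.0,
        uniform_prob_prior: bool = False,
    ):
        if isinstance(histories, pd.DataFrame):
            from .history import history_matrix

            histories = history_matrix(histories)
        Y = np.asarray(histories, dtype=np.int64)
        if Y.ndim != 2 or np.any((Y < 1) | (Y > 9)):
            raise ValueError("histories must be a 2-D matrix of codes 1..9")
        self.Y = Y
        first = np.full(Y.shape[0], -1, dtype=np.int64)
        for i in range(Y.shape[0]):
            obs = np.nonzero(Y[i] != NOT_OBSERVED)[0]
            if obs.size:
                first[i] = obs[0]
        self.first = first
        self.psi_prior_sd = float(psi_prior_sd)
        self.uniform_prob_prior = bool(uniform_prob_prior)
        self.support = observed_transition_support(Y)

    def log_posterior(self, theta: np.ndarray) -> float:
        return float(
            log_posterior(
                np.asarray(theta, float),
                self.Y,
                self.first,
                self.psi_prior_sd,
                self.uniform_prob_prior,
            )
        )

    def loglik(self, spec: ModelSpec) -> float:
        """Forward log-likelihood of the data at fixed parameter values."""
        Omega, Theta = spec.matrices()
        total = 0.0
        for i in range(self.Y.shape[0]):
            if self.first[i] >= 0:
                total += forward_loglik_one(self.Y[i], int(self.first[i]), Omega, Theta)
        return float(total)

    def _init_theta(self, rng: np.random.Generator, max_tries: int = 50) -> np.ndarray:
        for _ in range(max_tries):
            theta = np.empty(72)
            theta[:56] = rng.normal(-2.5, 0.5, size=56)  # diagonal-dominant start
            theta[56:] = rng.normal(1.5, 0.5, size=16)  # phi, p near 0.8
            if np.isfinite(self.log_posterior(theta)):
                return theta
        raise RuntimeError("could not find initial values with finite posterior")

    def _run_chain(
        self, seed: int, iterations: int, burn_in: int, thin: int
    ) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        theta = self._init_theta(rng)
        lp = self.log_posterior(theta)
        n_blocks = len(_BLOCKS)
        step = np.full(n_blocks, 0.25)
        acc = np.zeros(n_blocks)
        tries = np.zeros(n_blocks)
        n_keep = (iterations - burn_in) // thin
        draws = np.empty((n_keep, 72))
        k = 0
        for it in range(iterations):
            for b, idx in enumerate(_BLOCKS):
                prop = theta.copy()
                prop[idx] += rng.normal(0.0, step[b], size=len(idx))
                lp_prop = self.log_posterior(prop)
                tries[b] += 1
                if np.log(rng.random()) < lp_prop - lp:
                    theta, lp = prop, lp_prop
                    acc[b] += 1
            # adapt proposal scales toward 20-40% acceptance during burn-in
            if it < burn_in and (it + 1) % 50 == 0:
                rates = acc / np.maximum(tries, 1)
                step[rates > 0.40] *= 1.25
                step[rates < 0.20] /= 1.25
                acc[:] = 0
                tries[:] = 0
            if it >= burn_in and (it - burn_in) % thin == 0 and k < n_keep:
                draws[k] = theta
                k += 1
        return draws[:k], acc / np.maximum(tries, 1)

    def fit(
        self,
        chains: int = 3,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 5,
        seed: int = 0,
    ) -> MultistateResults:
        """Sample the posterior; returns draws, summaries, and R-hats.

        Defaults are the desk-scale configuration (3 chains x 20,000
        iterations, 5,000 burn-in, thin 5); the full-scale 3 x 450,000 /
        9,000 / 10 configuration is available through the arguments.
        """
        if chains < 1 or iterations <= burn_in or thin < 1:
            raise ValueError("invalid MCMC configuration")
        ss = np.random.SeedSequence(seed)
        chain_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(chains)]
        all_draws = []
        all_acc = []
        for cs in chain_seeds:
            d, a = self._run_chain(cs, iterations, burn_in, thin)
            all_draws.append(d)
            all_acc.append(a)
        theta_draws = np.stack(all_draws)  # (chains, n_keep, 72)
        C, D = theta_draws.shape[:2]
        psi = np.empty((C, D, 8, 8))
        phi = np.empty((C, D, 8))
        p = np.empty((C, D, 8))
        for c in range(C):
            for d in range(D):
                psi[c, d], phi[c, d], p[c, d] = theta_to_matrices(theta_draws[c, d])
        return MultistateResults(
            psi_draws=psi,
            phi_draws=phi,
            p_draws=p,
            support=self.support,
            acceptance=np.stack(all_acc),
            config={
                "chains": chains,
                "iterations": iterations,
                "burn_in": burn_in,
                "thin": thin,
                "seed": seed,
            },
        )


def fit_mcmc(
    histories,
    chains: int = 3,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> MultistateResults:
    """Functional wrapper over :class:`MultistateModel`."""
    return MultistateModel(histories, **model_kwargs).fit(
        chains=chains, iterations=iterations, burn_in=burn_in, thin=thin, seed=seed
    )
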