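"""CAVIaR: coordinate-ascent variational inference with isotonic regularization.

Infers synaptic connectivity from holographic ensemble-stimulation data.  The
observation model treats each trial's postsynaptic charge transfer y_k as a
noisy sum of latent presynaptic spikes weighted by synaptic strengths, with a
per-trial spontaneous current z_k:

    y_k ~ Normal(w' s_{:,k} + z_k, sigma^2)
    s_nk | phi_n ~ Bernoulli(sigmoid(phi_n0 I_nk - phi_n1))
    w_n ~ Normal(u, b^2),  sigma^-2 ~ Gamma(t_sh, t_ra),  phi_n ~ Normal(v, L)

The variational posterior factorizes over weights (multivariate normal),
spikes (independent Bernoulli), sigmoid coefficients (truncated bivariate
normal with independent positive marginals) and noise precision (gamma).
Beyond the conjugate coordinate updates, three mechanisms provide robustness:
(1) an isotonic plausibility rule — the PAVA-fitted power curve of each
neuron must exceed a minimum spike rate at maximum laser power, adaptively
raised by the estimated spontaneous event rate — applied immediately after
each neuron's spike update; (2) soft-thresholded estimation of spontaneous
currents constrained to be approximately orthogonal to the inferred spikes;
(3) masking of noise-only trials via a sample-autocorrelation statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .isotonic import pava
from .simulate import StimulusDesign, sigmoid

LOGIT_CLIP = 15.0


# ---------------------------------------------------------------------------
# hyperparameters and state


@dataclass
class ModelHyperparams:
    """Priors and algorithmic constants for CAVIaR.

    ``b2=None`` sets the weight-prior variance from a robust scale of the
    observations at fit time.  The sigmoid-coefficient prior is deliberately
    conservative (low spike probability at all powers): neurons only acquire
    high inferred spike rates when the likelihood supports them, which is
    what allows the plausibility rule to excise unconnected neurons.
    """

    u: float = 0.0
    b2: float | None = None
    t_sh: float = 1e-2
    t_ra: float = 1e-2
    prior_phi_mean: tuple = (0.02, 4.5)
    prior_phi_var: tuple = (0.0025, 4.0)   # diagonal of L
    theta_pava: float = 0.4
    mc_samples: int = 100
    tau_min: float = 0.5
    eps_spont: float = 0.05
    theta_orthog: float = 0.5
    burn_in: int = 15
    phase1_tol: float = 0.02
    max_iter: int = 40
    tol: float = 2e-3
    newton_iters: int = 25
    barrier_schedule: tuple = (10.0, 100.0, 1000.0)

    def validate(self):
        if self.b2 is not None and self.b2 <= 0:
            raise ValueError("b2 must be positive")
        if self.t_sh <= 0 or self.t_ra <= 0:
            raise ValueError("noise prior parameters must be positive")
        if not 0 <= self.theta_pava <= 1:
            raise ValueError("theta_pava must lie in [0, 1]")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if not 0 < self.eps_spont < 1:
            raise ValueError("eps_spont must lie in (0, 1)")


@dataclass
class VariationalState:
    """All variational posterior factors maintained by CAVIaR."""

    mu: np.ndarray             # (N,) weight posterior mean
    Omega: np.ndarray          # (N, N) weight posterior covariance
    lam: np.ndarray            # (N, K) spike posteriors in [0, 1]
    nu: np.ndarray             # (N, 2) sigmoid-coefficient posterior modes
    Sigma: np.ndarray          # (N, 2, 2) sigmoid-coefficient posterior covs
    theta_sh: float
    theta_ra: float
    z: np.ndarray              # (K,) spontaneous currents >= 0
    lam_spont: float = 0.0
    disconnected: np.ndarray = None   # (N,) bool, hard-excluded neurons
    mask: np.ndarray = None           # (K,) bool, True = trial usable

    @property
    def noise_precision(self) -> float:
        return self.theta_sh / self.theta_ra

    def check_invariants(self):
        assert np.all((self.lam >= 0) & (self.lam <= 1))
        assert np.all(self.z >= 0)
        assert np.allclose(self.Omega, self.Omega.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(self.Omega) > 0)
        assert np.all(self.nu > 0)


@dataclass
class PowerCurve:
    """Isotonic power curve for one neuron."""

    powers: np.ndarray        # levels actually used for this neuron
    mean_rates: np.ndarray    # lambda-bar per power
    fitted: np.ndarray        # PAVA fit, non-decreasing, in [0, 1]
    counts: np.ndarray        # trials per power

    def at_max_power(self) -> float:
        return float(self.fitted[-1]) if self.fitted.size else 0.0


@dataclass
class CaviarResult:
    state: VariationalState
    curves: list
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)

    @property
    def connected(self) -> np.ndarray:
        return self.state.mu != 0

    @property
    def weights(self) -> np.ndarray:
        return self.state.mu


# ---------------------------------------------------------------------------
# helpers


def sample_truncnorm_pos(mean, sd, size, rng: np.random.Generator):
    """Inverse-CDF samples from Normal(mean, sd^2) truncated to (0, inf)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lo = ndtr(-mean / sd)  # P(X <= 0)
    u = rng.random(size)
    p = lo + u * (1.0 - lo)
    return mean + sd * ndtri(np.clip(p, 1e-12, 1 - 1e-12))


def truncnorm_pos_mean(mean, sd):
    """Mean of Normal(mean, sd^2) truncated to (0, inf)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = -mean / sd
    phi = np.exp(-0.5 * a**2) / np.sqrt(2 * np.pi)
    return mean + sd * phi / np.maximum(ndtr(-a), 1e-300)


def trace_autocorrelation(trace: np.ndarray, lag: int = 1, std_floor: float = 0.1) -> float:
    """Lag-``lag`` sample autocorrelation; 0 for near-constant traces.

    Near-zero traces (e.g. demixed pure-noise windows) have no meaningful
    autocorrelation, so anything with standard deviation below ``std_floor``
    (pA) is scored 0 and will be masked.
    """
    x = np.asarray(trace, dtype=float)
    if x.std() < std_floor:
        return 0.0
    a = x[:-lag] - x[:-lag].mean()
    b = x[lag:] - x[lag:].mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def mask_trials(traces: np.ndarray, tau_min: float = 0.5) -> np.ndarray:
    """Boolean mask over trials; True = trial passes the statistic tau >= tau_min."""
    return np.array([trace_autocorrelation(t) >= tau_min for t in traces])


# ---------------------------------------------------------------------------
# individual updates


def init_state(
    design: StimulusDesign,
    y: np.ndarray,
    hyper: ModelHyperparams,
    rng: np.random.Generator | None = None,
) -> VariationalState:
    """Deterministic initialization: prior-parameterized factors."""
    n, k = design.powers.shape
    if y.shape != (k,):
        raise ValueError(f"y has shape {y.shape}, expected ({k},)")
    hyper.validate()
    b2 = _resolve_b2(hyper, y)
    v = np.asarray(hyper.prior_phi_mean)
    sd = np.sqrt(np.asarray(hyper.prior_phi_var))
    # means of the truncated-positive prior marginals (what the spike update
    # itself averages over)
    v_trunc = truncnorm_pos_mean(v, sd)
    lam = sigmoid(v_trunc[0] * design.powers - v_trunc[1])
    lam[design.powers == 0] = 0.0
    nu = np.tile(v, (n, 1))
    Sigma = np.tile(np.diag(hyper.prior_phi_var), (n, 1, 1))
    return VariationalState(
        mu=np.full(n, hyper.u, dtype=float),
        Omega=b2 * np.eye(n),
        lam=lam,
        nu=nu,
        Sigma=Sigma,
        theta_sh=hyper.t_sh,
        theta_ra=hyper.t_ra,
        z=np.zeros(k),
        lam_spont=0.0,
        disconnected=np.zeros(n, dtype=bool),
        mask=np.ones(k, dtype=bool),
    )


def _resolve_b2(hyper: ModelHyperparams, y: np.ndarray) -> float:
    if hyper.b2 is not None:
        return hyper.b2
    scale = np.percentile(np.abs(y), 95)
    return float(max(2.0 * scale, 10.0) ** 2)


def update_weights(state: VariationalState, y: np.ndarray, hyper: ModelHyperparams,
                   b2: float | None = None):
    """Conjugate block update of the weight posterior (mu, Omega).

    Uses the spontaneous-adjusted observations y - z: z_k is part of the
    trial mean in the observation model.
    """
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observations")
    lam = state.lam
    n = lam.shape[0]
    b2 = _resolve_b2(hyper, y) if b2 is None else b2
    c = state.noise_precision
    s_dm = lam @ lam.T
    d_diag = (lam * (1.0 - lam)).sum(axis=1)
    s_dm[np.diag_indices(n)] += d_diag
    prec = c * s_dm + np.eye(n) / b2
    yz = y - state.z
    rhs = c * (lam @ yz) + hyper.u / b2
    omega = np.linalg.inv(prec)
    omega = 0.5 * (omega + omega.T)
    state.Omega = omega
    state.mu = omega @ rhs
    state.mu[state.disconnected] = 0.0
    return state.mu, state.Omega


def update_spikes(
    state: VariationalState,
    neuron: int,
    y: np.ndarray,
    design: StimulusDesign,
    hyper: ModelHyperparams,
    rng: np.random.Generator,
    yhat: np.ndarray | None = None,
    use_weight_variance: bool = True,
):
    """Variational update of the spike posteriors of one neuron, all trials.

    The prior term is a Monte-Carlo estimate of E_q[logit f(phi0 I - phi1)]
    with phi sampled independently from its truncated positive marginals; the
    likelihood term couples the trial residual (excluding this neuron) with
    the posterior weight mean and variance.  Untargeted and masked trials
    stay at zero.
    """
    n_ix = neuron
    powers = design.powers[n_ix]
    targ = (powers > 0) & state.mask
    lam_old = state.lam[n_ix].copy()
    if state.disconnected[n_ix] or not targ.any():
        state.lam[n_ix, ~state.mask] = 0.0
        return state.lam[n_ix]
    if yhat is None:
        yhat = state.lam.T @ state.mu

    m = hyper.mc_samples
    sd = np.sqrt(np.maximum(np.diagonal(state.Sigma[n_ix]), 1e-12))
    phi0 = sample_truncnorm_pos(state.nu[n_ix, 0], sd[0], m, rng)
    phi1 = sample_truncnorm_pos(state.nu[n_ix, 1], sd[1], m, rng)
    # logit of the sigmoid is linear in phi, so the MC average is cheap
    prior_logit = float(np.mean(phi0)) * powers[targ] - float(np.mean(phi1))

    mu_n = state.mu[n_ix]
    beta2 = state.Omega[n_ix, n_ix] if use_weight_variance else 0.0
    c = state.noise_precision
    resid = (y[targ] - state.z[targ]) - (yhat[targ] - mu_n * lam_old[targ])
    like = c * (mu_n * resid - 0.5 * (mu_n**2 + beta2))
    logit = np.clip(prior_logit + like, -LOGIT_CLIP, LOGIT_CLIP)

    new = np.zeros_like(lam_old)
    new[targ] = sigmoid(logit)
    state.lam[n_ix] = new
    if yhat is not None:
        yhat += mu_n * (new - lam_old)
    return state.lam[n_ix]


def isotonic_power_curve(
    lam_n: np.ndarray,
    powers_n: np.ndarray,
    power_set: np.ndarray,
    mask: np.ndarray | None = None,
) -> PowerCurve:
    """Per-power mean inferred spike rates with a PAVA isotonic fit.

    Powers never used for this neuron (within the unmasked trials) are
    excluded from the fit with a warning.  Per-power means are weighted by
    trial counts so the pooled PAVA solution matches the trial-level
    least-squares objective.
    """
    mask = np.ones_like(lam_n, dtype=bool) if mask is None else mask
    levels, rates, counts = [], [], []
    for p in np.sort(np.asarray(power_set, dtype=float)):
        sel = (powers_n == p) & mask
        cnt = int(sel.sum())
        if cnt == 0:
            warnings.warn(f"power level {p} never used for this neuron; excluded")
            continue
        levels.append(p)
        rates.append(float(lam_n[sel].mean()))
        counts.append(cnt)
    levels = np.asarray(levels)
    rates = np.asarray(rates)
    counts = np.asarray(counts, dtype=float)
    fitted = pava(rates, counts) if rates.size else rates
    return PowerCurve(levels, rates, np.clip(fitted, 0.0, 1.0), counts)


def plausibility_check(curve: PowerCurve, hyper: ModelHyperparams, lam_spont: float) -> bool:
    """True if the isotonic spike rate at maximum power clears the adjusted
    threshold theta_PAVA + lambda_spont."""
    return curve.at_max_power() >= hyper.theta_pava + lam_spont


def apply_plausibility(
    state: VariationalState,
    neuron: int,
    design: StimulusDesign,
    hyper: ModelHyperparams,
) -> PowerCurve:
    """Evaluate one neuron's power curve; disconnect it if implausible.

    Two physical screens accompany the isotonic spike-rate rule: a neuron
    whose posterior mean weight is non-positive is implausible (currents are
    stored as non-negative magnitudes, so a negative weight only fits
    noise), and so is one whose per-spike charge lies below the observation
    noise standard deviation — such a "connection" cannot be distinguished
    from noise on any single trial, and spike posteriors aligned with noise
    excursions would otherwise let it hover at the plausibility threshold.
    """
    curve = isotonic_power_curve(
        state.lam[neuron], design.powers[neuron], design.power_set, state.mask
    )
    sigma = float(np.sqrt(state.theta_ra / state.theta_sh))
    if (state.mu[neuron] <= sigma
            or not plausibility_check(curve, hyper, state.lam_spont)):
        state.disconnected[neuron] = True
        state.mu[neuron] = 0.0
        state.lam[neuron] = 0.0
    return curve


def update_phi(
    state: VariationalState,
    neuron: int,
    design: StimulusDesign,
    hyper: ModelHyperparams,
):
    """Laplace update of one neuron's sigmoid-coefficient posterior.

    Finds the positive-orthant mode of the expected Bernoulli log-likelihood
    plus Gaussian prior via damped Newton iterations with a log barrier
    (sharpened over ``barrier_schedule``) and backtracking line search; the
    posterior covariance is the inverse Hessian at the mode.  Only targeted
    trials enter the likelihood.
    """
    n_ix = neuron
    powers = design.powers[n_ix]
    targ = (powers > 0) & state.mask
    v = np.asarray(hyper.prior_phi_mean)
    l_inv = np.diag(1.0 / np.asarray(hyper.prior_phi_var))
    if state.disconnected[n_ix] or not targ.any():
        state.nu[n_ix] = v
        state.Sigma[n_ix] = np.diag(hyper.prior_phi_var)
        return state.nu[n_ix], state.Sigma[n_ix]

    lam = state.lam[n_ix, targ]
    ii = powers[targ]
    x = np.column_stack([ii, -np.ones_like(ii)])  # f = sigmoid(x @ phi)

    def objective(phi, t):
        eta = x @ phi
        # stable log-likelihood: lam*log f + (1-lam)*log(1-f)
        ll = lam * eta - np.logaddexp(0.0, eta)
        pen = 0.5 * (phi - v) @ l_inv @ (phi - v)
        bar = -np.sum(np.log(phi)) / t
        return -ll.sum() + pen + bar

    phi = np.maximum(state.nu[n_ix], 1e-3)
    h = np.eye(2)
    for t in hyper.barrier_schedule:
        for _ in range(hyper.newton_iters):
            eta = x @ phi
            f = sigmoid(eta)
            grad = x.T @ (f - lam) + l_inv @ (phi - v) - 1.0 / (t * phi)
            w = f * (1.0 - f)
            h = (x * w[:, None]).T @ x + l_inv + np.diag(1.0 / (t * phi**2))
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                warnings.warn("Hessian not invertible; regularizing")
                step = np.linalg.solve(h + 1e-6 * np.eye(2), grad)
            # backtracking line search, keeping iterates positive
            kappa = 1.0
            f0 = objective(phi, t)
            gd = grad @ step
            while kappa > 1e-8:
                cand = phi - kappa * step
                if np.all(cand > 0) and objective(cand, t) <= f0 - 1e-4 * kappa * gd:
                    break
                kappa *= 0.5
            else:
                break
            phi = phi - kappa * step
            if np.linalg.norm(kappa * step) < 1e-9:
                break
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not PD at mode; using regularized inverse")
        cov = np.linalg.inv(h + 1e-6 * np.eye(2))
    state.nu[n_ix] = phi
    state.Sigma[n_ix] = 0.5 * (cov + cov.T)
    return state.nu[n_ix], state.Sigma[n_ix]


def update_noise(state: VariationalState, y: np.ndarray, hyper: ModelHyperparams):
    """Conjugate gamma update of the noise-precision posterior.

    E[(y - z - w's)^2] is evaluated analytically using the weight posterior
    second moments and the Bernoulli moments E[s_n] = lam_n, E[s_n^2] = lam_n.
    """
    lam = state.lam
    mu = state.mu
    omega = state.Omega
    k = y.shape[0]
    yz = y - state.z
    yhat = lam.T @ mu
    second = np.einsum("nk,nm,mk->k", lam, omega + np.outer(mu, mu), lam)
    diag_term = ((np.diag(omega) + mu**2)[:, None] * (lam - lam**2)).sum(axis=0)
    e_sq = yz**2 - 2.0 * yz * yhat + second + diag_term
    state.theta_sh = hyper.t_sh + 0.5 * k
    state.theta_ra = hyper.t_ra + 0.5 * float(e_sq.sum())
    return state.theta_sh, state.theta_ra


def soft_threshold(e, gamma):
    """S(e, gamma) = 0 if e <= gamma else e - gamma."""
    return np.where(e <= gamma, 0.0, e - gamma)


def update_spont(state: VariationalState, y: np.ndarray, hyper: ModelHyperparams):
    """Soft-thresholded spontaneous-current estimate.

    Positively rectified residuals are soft-thresholded with a penalty gamma
    shrunk until the residual norm is at most eps of the observed norm.
    Trials with appreciable inferred spiking (sum_n lam_nk > theta_orthog) or
    masked trials are forced to zero; the spontaneous rate estimate is the
    fraction of trials carrying a spontaneous current.

    Gamma is never shrunk below twice the posterior-mean noise standard
    deviation: residuals at the scale of the observation noise are not
    evidence of spontaneous events, and without the floor the shrink loop
    would label every noise excursion a spontaneous PSC whenever the
    eps criterion is unattainable.
    """
    lam = state.lam
    yhat = lam.T @ state.mu
    e = np.maximum(y - yhat, 0.0)
    blocked = (lam.sum(axis=0) > hyper.theta_orthog) | (~state.mask)
    e = np.where(blocked, 0.0, e)

    denom = float((y**2).sum())
    if denom == 0 or not e.any():
        state.z = np.zeros_like(y)
        state.lam_spont = 0.0
        return state.z, state.lam_spont

    sigma = float(np.sqrt(state.theta_ra / state.theta_sh))
    gamma_floor = 2.0 * sigma

    def ratio(g):
        return ((y - yhat - soft_threshold(e, g)) ** 2).sum() / denom

    gamma_hi = float(e.max())  # z = 0
    if ratio(gamma_hi) <= hyper.eps_spont:
        gamma = gamma_hi
    else:
        gamma = gamma_hi
        satisfied = False
        while gamma > gamma_floor:
            nxt = max(0.8 * gamma, gamma_floor)
            if ratio(nxt) <= hyper.eps_spont:
                # bisect for the largest penalty meeting the criterion
                lo, hi = nxt, gamma
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if ratio(mid) <= hyper.eps_spont:
                        lo = mid
                    else:
                        hi = mid
                gamma = lo
                satisfied = True
                break
            gamma = nxt
        if not satisfied:
            gamma = gamma_floor
    state.z = soft_threshold(e, gamma)
    state.lam_spont = float((state.z > 0).mean())
    return state.z, state.lam_spont


# ---------------------------------------------------------------------------
# the full algorithm


def fit(
    y: np.ndarray,
    design: StimulusDesign,
    hyper: ModelHyperparams | None = None,
    rng: np.random.Generator | None = None,
    traces: np.ndarray | None = None,
    plausibility: bool = True,
    spont: bool = True,
    masking: bool = True,
    verbose: bool = False,
) -> CaviarResult:
    """Run CAVIaR to convergence.

    Each outer iteration performs, in order: per-neuron spike updates in
    randomized neuron order, each immediately followed by the isotonic
    plausibility check (active once weights have been estimated, i.e. from
    the second iteration); the conjugate weight block update; per-neuron
    Laplace updates of the sigmoid coefficients; the noise update; and the
    spontaneous-current update.  Stops when the weight posterior mean is
    stable or after ``max_iter`` iterations.

    Parameters
    ----------
    y : (K,) postsynaptic charges (demixed-trace integrals).
    traces : optional (K, 900) demixed traces used for trial masking.
    plausibility, spont, masking : switch off individual robustness
        mechanisms (used by the spike-and-slab ablation baseline).
    """
    hyper = ModelHyperparams() if hyper is None else hyper
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, dtype=float)
    n, k = design.powers.shape

    state = init_state(design, y, hyper, rng)
    if masking and traces is not None:
        state.mask = mask_trials(traces, hyper.tau_min)
        state.lam[:, ~state.mask] = 0.0
    b2 = _resolve_b2(hyper, y)
    # warm start: calibrate the noise scale to the raw observations, then
    # estimate weights once from the prior-level spike probabilities, so the
    # first spike updates see a finite-variance, data-scaled posterior
    update_noise(state, y, hyper)
    update_weights(state, y, hyper, b2=b2)

    curves: list = [None] * n
    converged = False
    history = []
    n_it = 0
    active = False
    activation_it = None
    delta_prev = np.inf
    sigma_prev = np.inf
    for it in range(hyper.max_iter):
        n_it = it + 1
        # two-phase schedule: the plausibility rule, the spontaneous-current
        # estimation and the per-neuron power-curve refits activate only
        # once the plain coordinate updates have stabilized — both the
        # weight posterior and the noise scale (or after burn_in
        # iterations).  The noise-scale estimate contracts geometrically
        # over the first iterations, and judging power curves (or assigning
        # residuals to z) against a still-inflated noise scale would
        # disconnect genuine synapses that simply have not accumulated
        # evidence yet.
        sigma_now = float(np.sqrt(state.theta_ra / state.theta_sh))
        sigma_stable = abs(sigma_prev - sigma_now) < 0.05 * sigma_now
        sigma_prev = sigma_now
        if not active and (it >= hyper.burn_in or
                           (it >= 2 and sigma_stable and
                            delta_prev < hyper.phase1_tol *
                            max(1.0, float(np.max(np.abs(state.mu)))))):
            active = True
            activation_it = n_it
        mu_prev = state.mu.copy()
        yhat = state.lam.T @ state.mu
        order = rng.permutation(n)
        for n_ix in order:
            if state.disconnected[n_ix]:
                continue
            update_spikes(state, n_ix, y, design, hyper, rng, yhat=yhat,
                          use_weight_variance=active)
            if plausibility and active:
                mu_before = state.mu[n_ix]
                curves[n_ix] = apply_plausibility(state, n_ix, design, hyper)
                if state.disconnected[n_ix] and mu_before != 0.0:
                    yhat = state.lam.T @ state.mu
        update_weights(state, y, hyper, b2=b2)
        for n_ix in range(n):
            update_phi(state, n_ix, design, hyper)
        update_noise(state, y, hyper)
        if spont and active:
            update_spont(state, y, hyper)
        delta = float(np.max(np.abs(state.mu - mu_prev)))
        delta_prev = delta
        scale = max(1.0, float(np.max(np.abs(state.mu))))
        history.append({"iter": n_it, "delta_mu": delta, "lam_spont": state.lam_spont,
                        "n_disconnected": int(state.disconnected.sum()),
                        "active": active})
        if verbose:
            print(f"[caviar] iter {n_it} delta_mu={delta:.4g} "
                  f"spont={state.lam_spont:.3f} disc={int(state.disconnected.sum())} "
                  f"active={active}")
        if (active and activation_it is not None and n_it >= activation_it + 2
                and delta < hyper.tol * scale):
            converged = True
            break

    # final curves for all still-connected neurons
    for n_ix in range(n):
        if curves[n_ix] is None and not state.disconnected[n_ix]:
            curves[n_ix] = isotonic_power_curve(
                state.lam[n_ix], design.powers[n_ix], design.power_set, state.mask
            )
    # hard-zero the disconnected weights (plausibility rule's contract)
    state.mu[state.disconnected] = 0.0
    if not converged:
        warnings.warn(f"CAVIaR did not converge in {hyper.max_iter} iterations")
    return CaviarResult(state, curves, converged, n_it, history)
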