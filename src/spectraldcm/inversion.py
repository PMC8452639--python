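"""Variational-Laplace spectral model inversion and model comparison.

The observed data feature is the log power spectral density of a field
recording on a fixed frequency grid.  The generative model predicts this
feature from the canonical microcircuit's 18 free neuronal parameters
(4 tau, 10 gamma magnitudes, 4 sigma) through a log-scaling
parameterization ``theta = theta_bar * exp(lambda)``, with independent
Gaussian observation error of unknown precision ``exp(h)`` on each
frequency bin.

Inference maximizes the variational free energy

    F = E_q[log p(y | lambda, h)] - KL(q(lambda) || p(lambda))
                                  - KL(q(h) || p(h))

over a Gaussian posterior ``q(lambda) = N(mu, Sigma)`` and
``q(h) = N(m_h, v_h)`` by Gauss-Newton ascent with Levenberg-Marquardt
damping; F approximates the log model evidence and differences in F between
models are log Bayes factors.

The public surface follows the Model/Results convention: build a
:class:`SpectralCMC` from data features, call :meth:`SpectralCMC.fit`, and
read estimates, credible intervals and the free energy off the returned
:class:`SpectralCMCResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import cmc
from .cmc import CMCParameters, SpectralDensity, UnstableModelError
from .ephys import TraceRecording, WELCH_OVERLAP, WELCH_WINDOW_S

__all__ = [
    "PARAM_NAMES",
    "ParameterDensity",
    "FitSettings",
    "InversionResult",
    "SpectralCMC",
    "SpectralCMCResult",
    "data_features",
    "variational_laplace",
    "free_energy_components",
    "compare_models",
    "empirical_prior_from",
    "fit_condition_sequence",
    "default_prior",
]

#: Names of the 18 free neuronal parameters, in the lambda-vector order.
PARAM_NAMES: tuple[str, ...] = (
    "tau_ss", "tau_ii", "tau_sp", "tau_dp",
    *[f"gamma{i}" for i in range(1, 11)],
    "sigma_ss", "sigma_ii", "sigma_sp", "sigma_dp",
)


@dataclass(frozen=True)
class ParameterDensity:
    """Gaussian density over log-scaling parameters lambda."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        d = mean.size
        if cov.shape != (d, d):
            raise ValueError("covariance shape must match mean dimension")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = float(np.min(np.linalg.eigvalsh(cov)))
        if eigmin < -1e-10 * max(1.0, float(np.max(np.abs(cov)))):
            raise ValueError("covariance must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterDensity":
        return cls(np.asarray(d["mean"], float), np.asarray(d["cov"], float))


def default_prior(dim: int = 18, var: float = 1.0 / 16.0) -> ParameterDensity:
    """Baseline shrinkage prior lambda ~ N(0, var I) (sd 0.25 per parameter)."""
    return ParameterDensity(np.zeros(dim), var * np.eye(dim))


@dataclass(frozen=True)
class FitSettings:
    """Settings of the variational-Laplace inversion.

    ``freq_range``/``freq_step`` define the fit grid (defaults 1-100 Hz at
    0.5 Hz).  Convergence requires ``|dF| < f_tolerance`` on
    ``converge_streak`` consecutive accepted iterations.  When
    ``fix_noise_logprec`` is set the observation-noise log-precision is held
    at that value instead of being estimated (used for closed-form checks).
    """

    freq_range: tuple[float, float] = (1.0, 100.0)
    freq_step: float = 0.5
    max_iter: int = 128
    f_tolerance: float = 0.01
    converge_streak: int = 4
    lm_damping_init: float = 1.0
    fd_step: float = 1e-3
    noise_logprec_prior: tuple[float, float] = (0.0, 1.0)  # (mean, variance)
    fix_noise_logprec: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.f_tolerance <= 0:
            raise ValueError("f_tolerance must be positive")
        if self.freq_step <= 0 or self.freq_range[0] >= self.freq_range[1]:
            raise ValueError("invalid frequency grid")

    @property
    def freqs(self) -> np.ndarray:
        lo, hi = self.freq_range
        n = int(np.floor((hi - lo) / self.freq_step + 1e-9)) + 1
        return lo + self.freq_step * np.arange(n)


def data_features(
    data: TraceRecording | SpectralDensity,
    settings: FitSettings | None = None,
) -> np.ndarray:
    """Log-PSD data feature on the fit grid.

    A :class:`TraceRecording` is reduced by Welch (2 s Hann, 50% overlap) and
    the log-PSD interpolated onto the grid; a :class:`SpectralDensity`
    already on the grid passes through unchanged (otherwise it is
    log-interpolated).  The input must cover the requested frequency range.
    """
    settings = settings or FitSettings()
    grid = settings.freqs
    if isinstance(data, TraceRecording):
        from scipy import signal as _signal

        nyq = data.sampling_rate / 2.0
        if grid[-1] > nyq:
            raise ValueError(
                f"fit range extends to {grid[-1]} Hz, above Nyquist {nyq} Hz"
            )
        nper = min(int(round(WELCH_WINDOW_S * data.sampling_rate)), data.samples.size)
        f, p = _signal.welch(
            data.samples, fs=data.sampling_rate, window="hann",
            nperseg=nper, noverlap=int(nper * WELCH_OVERLAP), detrend="constant",
        )
        good = p > 0
        return np.interp(grid, f[good], np.log(p[good]))
    if isinstance(data, SpectralDensity):
        if data.freqs[0] > grid[0] + 1e-9 or data.freqs[-1] < grid[-1] - 1e-9:
            raise ValueError("spectral density does not cover the fit range")
        if data.freqs.size == grid.size and np.allclose(data.freqs, grid):
            return np.log(data.values)
        return np.interp(grid, data.freqs, np.log(data.values))
    raise TypeError("data must be a TraceRecording or SpectralDensity")


@dataclass
class InversionResult:
    """Raw output of :func:`variational_laplace`."""

    posterior: ParameterDensity
    free_energy: float
    f_trajectory: np.ndarray
    noise_logprec_posterior: tuple[float, float]  # (mean, variance)
    converged: bool
    n_iter: int
    accuracy: float
    complexity: float
    prior: ParameterDensity
    prediction: np.ndarray | None = None


def _finite_diff_jacobian(forward, lam, g0, step):
    d = lam.size
    J = np.empty((g0.size, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = step
        try:
            gp = forward(lam + e)
            gm = forward(lam - e)
            J[:, j] = (gp - gm) / (2.0 * step)
        except (UnstableModelError, FloatingPointError, OverflowError):
            # one-sided fallback at the stability boundary
            try:
                gp = forward(lam + e)
                J[:, j] = (gp - g0) / step
            except (UnstableModelError, FloatingPointError, OverflowError):
                gm = forward(lam - e)
                J[:, j] = (g0 - gm) / step
    return J


def _try_forward(forward, lam):
    try:
        g = forward(lam)
    except (UnstableModelError, FloatingPointError, OverflowError):
        return None
    if not np.all(np.isfinite(g)):
        return None
    return g


def _update_noise_hyper(E_r, n, mh, vh, h0, v0):
    """Coordinate-ascent update of q(h) = N(mh, vh) given expected sq. error."""
    for _ in range(32):
        mh_old = mh
        # Newton on concave d/dmh: -0.5 e^{mh+vh/2} E_r + n/2 - (mh-h0)/v0
        for _ in range(64):
            w = np.exp(mh + vh / 2.0)
            grad = -0.5 * w * E_r + 0.5 * n - (mh - h0) / v0
            hess = -0.5 * w * E_r - 1.0 / v0
            step = grad / hess
            mh = mh - step
            if abs(step) < 1e-10:
                break
        vh = 1.0 / (0.5 * np.exp(mh + vh / 2.0) * E_r + 1.0 / v0)
        if abs(mh - mh_old) < 1e-10:
            break
    return mh, vh


def _free_energy(r, J, Sigma, prior, mu, mh, vh, h_fixed, h0, v0):
    """Variational free energy and its accuracy/complexity split."""
    n = r.size
    E_r = float(r @ r + np.einsum("ij,jk,ik->", J, Sigma, J))
    if h_fixed is not None:
        Eh = np.exp(h_fixed)
        mh_eff = h_fixed
        kl_h = 0.0
    else:
        Eh = np.exp(mh + vh / 2.0)
        mh_eff = mh
        kl_h = 0.5 * (vh / v0 + (mh - h0) ** 2 / v0 - 1.0 + np.log(v0 / vh))
    accuracy = -0.5 * Eh * E_r + 0.5 * n * (mh_eff - np.log(2.0 * np.pi))
    dmu = mu - prior.mean
    Pi0 = np.linalg.inv(prior.cov)
    sign0, logdet0 = np.linalg.slogdet(prior.cov)
    signp, logdetp = np.linalg.slogdet(Sigma)
    kl_lam = 0.5 * (
        np.trace(Pi0 @ Sigma) + dmu @ Pi0 @ dmu - mu.size + logdet0 - logdetp
    )
    return accuracy - kl_lam - kl_h, accuracy, kl_lam + kl_h


def variational_laplace(
    features: np.ndarray,
    forward: Callable[[np.ndarray], np.ndarray],
    prior: ParameterDensity,
    settings: FitSettings | None = None,
) -> InversionResult:
    """Fit ``features = forward(lambda) + noise`` by variational Laplace.

    ``forward`` maps a lambda vector to a predicted feature vector; it may
    raise :class:`~spectraldcm.cmc.UnstableModelError` for invalid
    parameters, in which case the proposed step is rejected and the
    Levenberg-Marquardt damping increased (never an exception to the
    caller).  Accepted steps never decrease the free energy; convergence is
    declared after ``converge_streak`` consecutive accepted steps with
    ``|dF| < f_tolerance``.
    """
    settings = settings or FitSettings()
    y = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("features must be finite")
    mu = prior.mean.copy()
    Pi0 = np.linalg.inv(prior.cov)
    h0, v0 = settings.noise_logprec_prior
    h_fixed = settings.fix_noise_logprec
    mh = h0 if h_fixed is None else h_fixed
    vh = v0 if h_fixed is None else 0.0

    g = _try_forward(forward, mu)
    if g is None:
        # prior mean lies in an unstable region: start from the nearest
        # feasible point on the segment towards the origin of lambda space
        for c in np.linspace(0.9, 0.0, 10):
            mu_try = c * prior.mean
            g = _try_forward(forward, mu_try)
            if g is not None:
                mu = mu_try
                break
        if g is None:
            raise ValueError(
                "forward model is invalid at the prior mean and at every "
                "shrunken starting point towards the origin"
            )
    if g.shape != y.shape:
        raise ValueError("prior dimension or feature grid mismatch")
    J = _finite_diff_jacobian(forward, mu, g, settings.fd_step)
    r = y - g

    def _posterior_cov(J, Eh):
        return np.linalg.inv(Eh * (J.T @ J) + Pi0)

    def _hyper_and_F(r, J, mu, mh, vh):
        if h_fixed is None:
            for _ in range(8):
                Sigma = _posterior_cov(J, np.exp(mh + vh / 2.0))
                E_r = float(r @ r + np.einsum("ij,jk,ik->", J, Sigma, J))
                mh_new, vh_new = _update_noise_hyper(E_r, y.size, mh, vh, h0, v0)
                if abs(mh_new - mh) < 1e-9:
                    mh, vh = mh_new, vh_new
                    break
                mh, vh = mh_new, vh_new
            Sigma = _posterior_cov(J, np.exp(mh + vh / 2.0))
        else:
            Sigma = _posterior_cov(J, np.exp(h_fixed))
        F, acc, cmp_ = _free_energy(r, J, Sigma, prior, mu, mh, vh, h_fixed, h0, v0)
        return F, acc, cmp_, Sigma, mh, vh

    F, acc, cmp_, Sigma, mh, vh = _hyper_and_F(r, J, mu, mh, vh)
    traj = [F]
    damping = settings.lm_damping_init
    streak = 0
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        Eh = np.exp(mh + vh / 2.0) if h_fixed is None else np.exp(h_fixed)
        grad = Eh * (J.T @ r) - Pi0 @ (mu - prior.mean)
        H = Eh * (J.T @ J) + Pi0
        try:
            delta = np.linalg.solve(H + damping * np.eye(mu.size), grad)
        except np.linalg.LinAlgError:
            damping *= 2.0
            continue
        mu_c = mu + delta
        g_c = _try_forward(forward, mu_c)
        accepted = False
        if g_c is not None:
            J_c = _finite_diff_jacobian(forward, mu_c, g_c, settings.fd_step)
            r_c = y - g_c
            F_c, acc_c, cmp_c, Sigma_c, mh_c, vh_c = _hyper_and_F(
                r_c, J_c, mu_c, mh, vh
            )
            if np.isfinite(F_c) and F_c >= F:
                dF = F_c - F
                mu, g, J, r = mu_c, g_c, J_c, r_c
                F, acc, cmp_, Sigma, mh, vh = F_c, acc_c, cmp_c, Sigma_c, mh_c, vh_c
                traj.append(F)
                damping *= 0.7
                accepted = True
                streak = streak + 1 if dF < settings.f_tolerance else 0
                if streak >= settings.converge_streak:
                    converged = True
                    break
        if not accepted:
            damping *= 2.0
            if damping > 1e12:  # step size has collapsed; nothing left to gain
                converged = True
                break

    posterior = ParameterDensity(mu, 0.5 * (Sigma + Sigma.T))
    return InversionResult(
        posterior=posterior,
        free_energy=float(F),
        f_trajectory=np.asarray(traj),
        noise_logprec_posterior=(float(mh), float(vh)),
        converged=converged,
        n_iter=it,
        accuracy=float(acc),
        complexity=float(cmp_),
        prior=prior,
        prediction=g.copy(),
    )


def free_energy_components(result: InversionResult) -> tuple[float, float]:
    """(accuracy, complexity) with F = accuracy - complexity, complexity >= 0."""
    return result.accuracy, result.complexity


def compare_models(
    f_values: Sequence[float],
    labels: Sequence[str] | None = None,
):
    """Fixed-effects Bayesian model comparison from free energies.

    Returns a DataFrame with the free energy relative to the best model
    (``delta_f``), Bayes factors against the best model and posterior model
    probabilities (softmax of F under uniform model priors).
    """
    import pandas as pd

    f = np.asarray(f_values, dtype=float)
    if f.size < 2:
        raise ValueError("model comparison needs at least two models")
    if labels is None:
        labels = [f"model_{i}" for i in range(f.size)]
    delta = f - f.max()
    w = np.exp(delta)
    prob = w / w.sum()
    return pd.DataFrame(
        {
            "free_energy": f,
            "delta_f": delta,
            "bayes_factor": w,
            "posterior_prob": prob,
        },
        index=list(labels),
    )


def empirical_prior_from(
    posterior: ParameterDensity, base_prior: ParameterDensity
) -> ParameterDensity:
    """Chain posterior expectations into the next condition's prior.

    Only the means are carried over; the covariance is reset to the base
    prior's, so each condition is shrunk by the same amount around the
    previous condition's estimate.
    """
    if posterior.dim != base_prior.dim:
        raise ValueError("dimension mismatch between posterior and base prior")
    return ParameterDensity(posterior.mean.copy(), base_prior.cov.copy())


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class SpectralCMC:
    """Canonical-microcircuit spectral model of a field recording.

    Parameters
    ----------
    log_psd : observed log power spectral density on ``settings.freqs``.
    base_params : the baseline parameter set theta_bar; fitted parameters
        are multiplicative deviations ``theta = theta_bar * exp(lambda)``.
    prior : Gaussian prior over lambda (default: N(0, 1/16) per parameter).
    settings : inversion settings (fit grid, tolerances, damping).
    tie_sigma : fit one shared sigmoid-slope deviation for all four
        populations instead of one per population.
    """

    def __init__(
        self,
        log_psd: np.ndarray,
        base_params: CMCParameters | None = None,
        prior: ParameterDensity | None = None,
        settings: FitSettings | None = None,
        tie_sigma: bool = False,
    ):
        self.settings = settings or FitSettings()
        self.endog = np.asarray(log_psd, dtype=float)
        self.freqs = self.settings.freqs
        if self.endog.shape != self.freqs.shape:
            raise ValueError(
                f"log_psd has {self.endog.size} points but the fit grid has "
                f"{self.freqs.size}"
            )
        self.base_params = base_params or CMCParameters()
        self.tie_sigma = tie_sigma
        self.k_params = 15 if tie_sigma else 18
        self.param_names = (
            list(PARAM_NAMES[:14]) + ["sigma"] if tie_sigma else list(PARAM_NAMES)
        )
        self.prior = prior or default_prior(self.k_params)
        if self.prior.dim != self.k_params:
            raise ValueError(
                f"prior dimension {self.prior.dim} != {self.k_params} free parameters"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_trace(cls, trace: TraceRecording, **kwargs) -> "SpectralCMC":
        """Build the model from a raw recording via Welch data features."""
        settings = kwargs.get("settings") or FitSettings()
        kwargs["settings"] = settings
        return cls(data_features(trace, settings), **kwargs)

    @classmethod
    def from_psd(cls, psd: SpectralDensity, **kwargs) -> "SpectralCMC":
        settings = kwargs.get("settings") or FitSettings()
        kwargs["settings"] = settings
        return cls(data_features(psd, settings), **kwargs)

    # -- forward model ----------------------------------------------------

    def _expand_lambda(self, lam: np.ndarray) -> np.ndarray:
        if not self.tie_sigma:
            return lam
        return np.concatenate([lam[:14], np.full(4, lam[14])])

    def predict(self, lam: np.ndarray) -> np.ndarray:
        """Predicted log-PSD at log-scaling parameters ``lam``."""
        params = self.base_params.with_scaling(self._expand_lambda(np.asarray(lam)))
        psd = cmc.predict_psd(params, self.freqs)
        return np.log(psd.values)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "SpectralCMCResult":
        raw = variational_laplace(self.endog, self.predict, self.prior, self.settings)
        return SpectralCMCResult(self, raw)


class SpectralCMCResult:
    """Results of a variational-Laplace fit of :class:`SpectralCMC`."""

    def __init__(self, model: SpectralCMC, raw: InversionResult):
        self.model = model
        self.raw = raw

    # -- estimates --------------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """Posterior mean of lambda (log scaling relative to the baseline)."""
        return self.raw.posterior.mean

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviations of lambda."""
        return self.raw.posterior.sd()

    @property
    def posterior(self) -> ParameterDensity:
        return self.raw.posterior

    @property
    def free_energy(self) -> float:
        return self.raw.free_energy

    @property
    def f_trajectory(self) -> np.ndarray:
        return self.raw.f_trajectory

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def noise_logprec_posterior(self) -> tuple[float, float]:
        return self.raw.noise_logprec_posterior

    @property
    def fitted_params(self) -> CMCParameters:
        """The scaled parameter set at the posterior mean."""
        return self.model.base_params.with_scaling(
            self.model._expand_lambda(self.params)
        )

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Central (1 - alpha) credible intervals for lambda, shape (k, 2)."""
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        sd = self.bse
        return np.column_stack([self.params - z * sd, self.params + z * sd])

    def free_energy_components(self) -> tuple[float, float]:
        return free_energy_components(self.raw)

    def fittedvalues(self) -> np.ndarray:
        """Predicted log-PSD at the posterior mean."""
        return self.model.predict(self.params)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        acc, cmp_ = self.free_energy_components()
        lines = [
            "Spectral canonical-microcircuit fit (variational Laplace)",
            "=" * 62,
            f"n frequencies: {self.model.freqs.size}   "
            f"grid: {self.model.freqs[0]:g}-{self.model.freqs[-1]:g} Hz",
            f"free energy: {self.free_energy:.3f}   "
            f"(accuracy {acc:.3f}, complexity {cmp_:.3f})",
            f"converged: {self.converged}   iterations: {self.raw.n_iter}",
            "noise log-precision: "
            f"{self.noise_logprec_posterior[0]:.3f} "
            f"(var {self.noise_logprec_posterior[1]:.3g})",
            "-" * 62,
            f"{'parameter':<12}{'lambda':>10}{'sd':>10}{'scale e^l':>12}",
        ]
        ci = self.conf_int()
        for name, lam, sd in zip(self.model.param_names, self.params, self.bse):
            lines.append(f"{name:<12}{lam:>10.4f}{sd:>10.4f}{np.exp(lam):>12.4f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted log-PSD."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.freqs, self.model.endog, label="observed", lw=1.5)
        ax.plot(self.model.freqs, self.fittedvalues(), "--", label="fitted", lw=1.5)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("log PSD")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Condition sequencing (control -> interictal -> ictal)
# ---------------------------------------------------------------------------


@dataclass
class ConditionSequenceResult:
    """Output of :func:`fit_condition_sequence`."""

    control: SpectralCMCResult
    interictal: SpectralCMCResult          # refit of the winning model
    ictal: SpectralCMCResult
    f_table: "object"                      # pandas.DataFrame, one row per model
    winning_spec: "object"                 # priors.ModelSpec
    per_model: dict

    @property
    def state_lambdas(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.control.params,
            self.interictal.params,
            self.ictal.params,
        )


def fit_condition_sequence(
    features_control: np.ndarray,
    features_interictal: np.ndarray,
    features_ictal: np.ndarray,
    model_space,
    settings: FitSettings | None = None,
    base_params: CMCParameters | None = None,
    shifts: dict | None = None,
    base_prior: ParameterDensity | None = None,
):
    """Three-stage empirical-prior fitting across disease conditions.

    Stage 1 fits the control spectrum from the default priors.  Stage 2 fits
    the interictal spectrum once per model in ``model_space``: each model's
    priors are the stage-1 empirical priors with the microscale-derived log
    shifts applied to its informed parameter subsets; the winner maximizes
    the free energy.  Stage 3 fits the ictal spectrum with the winning
    model's posterior expectations as empirical priors.

    ``shifts`` maps group name ('gamma', 'tau', 'sigma') to a log shift, as
    produced by :func:`spectraldcm.priors.shifts_from_contrast`.
    """
    import pandas as pd

    from .priors import informed_priors

    settings = settings or FitSettings()
    base_params = base_params or CMCParameters()
    base_prior = base_prior or default_prior(18)
    shifts = shifts or {"gamma": 0.0, "tau": 0.0, "sigma": 0.0}

    m1 = SpectralCMC(features_control, base_params, base_prior, settings)
    res_control = m1.fit()
    emp = empirical_prior_from(res_control.posterior, base_prior)

    rows = []
    per_model = {}
    for spec in model_space.specs:
        prior_m = informed_priors(emp, spec, shifts)
        m2 = SpectralCMC(features_interictal, base_params, prior_m, settings)
        res_m = m2.fit()
        per_model[spec.name] = res_m
        rows.append({"model": spec.name, "free_energy": res_m.free_energy,
                     "converged": res_m.converged})
    f_table = pd.DataFrame(rows).set_index("model")
    win_name = f_table["free_energy"].idxmax()
    winning_spec = next(s for s in model_space.specs if s.name == win_name)
    res_inter = per_model[win_name]

    prior3 = empirical_prior_from(res_inter.posterior, base_prior)
    m3 = SpectralCMC(features_ictal, base_params, prior3, settings)
    res_ictal = m3.fit()

    return ConditionSequenceResult(
        control=res_control,
        interictal=res_inter,
        ictal=res_ictal,
        f_table=f_table,
        winning_spec=winning_spec,
        per_model=per_model,
    )
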