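"""Group-based trajectory modelling of response speed.

A finite mixture of K latent groups, each following its own polynomial mean
trajectory over coded time with normally distributed residuals:

    y_it | group j  ~  Normal( sum_m beta_jm * t^m ,  sigma^2 )

A participant's observations are conditionally independent given the group,
so the marginal log-likelihood is

    log L = sum_i log sum_j pi_j prod_t phi( (y_it - mu_j(t_it)) / sigma ) / sigma

evaluated with log-sum-exp stabilisation.  Estimation is by EM on unbalanced
panels: the E-step computes posterior group responsibilities per participant,
the M-step solves a weighted polynomial least-squares problem per group,
updates the mixing proportions from the responsibility means, and pools the
weighted residuals for the noise SD (shared across groups by default).  The
number of groups is selected by BIC in the convention where the criterion is
log L - 0.5 k ln(n); "largest negative BIC" then means maximal BIC.

The outcome density is a plain normal rather than the censored normal of the
classic SAS implementation: response speeds here are strictly positive and
uncensored, so censoring machinery would be inert.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .ingest import SpeedSeries

__all__ = [
    "GbtmSpec",
    "GbtmModel",
    "PosteriorAssignment",
    "loglik",
    "fit_em",
    "bic",
    "select_k",
    "posteriors",
]

_LOG_2PI = math.log(2.0 * math.pi)
_PI_FLOOR = 1e-6


@dataclass(frozen=True)
class GbtmSpec:
    """Fitting specification: K groups, polynomial order, EM controls."""

    K: int = 3
    order: int = 3
    shared_sigma: bool = True
    n_starts: int = 3
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    bic_n: str = "participants"  # or "observations"

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if not 0 <= self.order <= 3:
            raise ValueError("polynomial order must be in 0..3")
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.bic_n not in ("participants", "observations"):
            raise ValueError("bic_n must be 'participants' or 'observations'")


@dataclass
class GbtmModel:
    """A fitted K-group trajectory mixture.

    ``beta`` is K x (order+1), ascending powers of coded time; ``sigma`` is a
    scalar when shared, else one SD per group.  ``bic`` uses the convention
    loglik - 0.5 * n_params * ln(n); larger (less negative) is better.
    ``loglik_path`` records the EM log-likelihood sequence of the winning
    start, for monotonicity diagnostics.
    """

    pi: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray  # shape () if shared, (K,) otherwise
    shared_sigma: bool
    order: int
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_participants: int
    n_observations: int = 0
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)
    collapsed: bool = False

    @property
    def K(self) -> int:
        return len(self.pi)

    def mean_at(self, times) -> np.ndarray:
        """Fitted group mean speeds, shape K x len(times)."""
        times = np.asarray(times, dtype=float)
        return np.vstack(
            [np.polynomial.polynomial.polyval(times, b) for b in self.beta]
        )

    def derivative_at(self, times) -> np.ndarray:
        """d mu_j / dt, shape K x len(times)."""
        times = np.asarray(times, dtype=float)
        return np.vstack(
            [
                np.polynomial.polynomial.polyval(
                    times, np.polynomial.polynomial.polyder(b)
                )
                for b in self.beta
            ]
        )

    def as_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "sigma": np.atleast_1d(self.sigma).tolist(),
            "shared_sigma": self.shared_sigma,
            "order": self.order,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "collapsed": self.collapsed,
            "n_participants": self.n_participants,
            "n_observations": self.n_observations,
            "n_iter": self.n_iter,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class PosteriorAssignment:
    """Posterior group-membership probabilities and max-posterior hard labels."""

    participant_ids: tuple[str, ...]
    posterior: np.ndarray  # n x K, rows sum to 1
    hard_label: dict[str, int]
    avg_posterior: np.ndarray  # per assigned group, mean of the max posterior


class _Panel:
    """Speed series packed into flat arrays, observations grouped by participant."""

    def __init__(self, series: list[SpeedSeries], order: int):
        if not series:
            raise ValueError("no speed series supplied")
        self.ids = tuple(s.participant_id for s in series)
        lens = np.array([len(s) for s in series])
        self.n = len(series)
        self.starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        self.y = np.concatenate([s.speeds for s in series])
        self.t = np.concatenate([s.times for s in series])
        self.lens = lens
        # Vandermonde design in ascending powers of coded time
        self.X = np.vander(self.t, order + 1, increasing=True)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def _participant_logdens(panel: _Panel, beta: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log prod_t phi(...) per participant and group; shape n x K."""
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    if (sig <= 0).any():
        raise ValueError("sigma must be positive")
    K = beta.shape[0]
    if sig.size == 1:
        sig = np.repeat(sig, K)
    mu = panel.X @ beta.T  # n_obs x K
    z = (panel.y[:, None] - mu) / sig[None, :]
    obs_ll = -0.5 * _LOG_2PI - np.log(sig)[None, :] - 0.5 * z * z
    return np.add.reduceat(obs_ll, panel.starts, axis=0)


def loglik(model: GbtmModel, series: list[SpeedSeries]) -> float:
    """Mixture log-likelihood of the series under the model (log-sum-exp stabilised)."""
    panel = _Panel(series, model.order)
    return _mixture_loglik(panel, model.pi, model.beta, model.sigma)[0]


def _mixture_loglik(panel, pi, beta, sigma):
    part = _participant_logdens(panel, beta, sigma)
    with np.errstate(divide="ignore"):
        logpost = np.log(pi)[None, :] + part
    lse = logsumexp(logpost, axis=1)
    return float(lse.sum()), logpost, lse


def _m_step(panel: _Panel, resp: np.ndarray, shared_sigma: bool):
    """Weighted polynomial least squares per group; pooled residual SD."""
    K = resp.shape[1]
    p = panel.X.shape[1]
    w_obs = np.repeat(resp, panel.lens, axis=0)  # n_obs x K
    beta = np.empty((K, p))
    ss = np.empty(K)
    wsum = np.empty(K)
    for j in range(K):
        sw = np.sqrt(w_obs[:, j])
        coef, *_ = np.linalg.lstsq(panel.X * sw[:, None], panel.y * sw, rcond=None)
        beta[j] = coef
        resid = panel.y - panel.X @ coef
        ss[j] = float(w_obs[:, j] @ (resid * resid))
        wsum[j] = float(w_obs[:, j].sum())
    pi = resp.mean(axis=0)
    collapsed = bool((pi < _PI_FLOOR).any())
    pi = np.maximum(pi, _PI_FLOOR)
    pi = pi / pi.sum()
    if shared_sigma:
        sigma = np.sqrt(ss.sum() / panel.n_obs)
        sigma = np.asarray(max(sigma, 1e-8))
    else:
        sigma = np.sqrt(np.maximum(ss / np.maximum(wsum, 1e-12), 1e-16))
    return pi, beta, sigma, collapsed


def _initial_resp(panel: _Panel, K: int, start: int, rng: np.random.Generator) -> np.ndarray:
    """Hard quantile-block assignment ranked by per-participant mean speed with
    a linear-trend tiebreak; starts after the first perturb the ranking scores."""
    means = np.add.reduceat(panel.y, panel.starts) / panel.lens
    slopes = np.zeros(panel.n)
    for i, (s, ln) in enumerate(zip(panel.starts, panel.lens)):
        if ln > 1:
            tt = panel.t[s : s + ln]
            yy = panel.y[s : s + ln]
            slopes[i] = np.polyfit(tt, yy, 1)[0]
    score = means.copy()
    if start > 0:
        spread = max(float(means.std()), 1e-3)
        score = means + rng.normal(0.0, 0.5 * spread, size=panel.n)
    order = np.lexsort((slopes, score))
    resp = np.zeros((panel.n, K))
    for j, block in enumerate(np.array_split(order, K)):
        resp[block, j] = 1.0
    return resp


def fit_em(series: list[SpeedSeries], spec: GbtmSpec) -> GbtmModel:
    """Fit the K-group mixture by EM with multiple restarts.

    Returns the highest-log-likelihood solution across ``spec.n_starts``
    initialisations, with groups relabelled by ascending intercept so reported
    labels are deterministic.  If no start converges within ``max_iter``, the
    best iterate is returned flagged ``converged=False``.
    """
    spec.validate()
    panel = _Panel(series, spec.order)
    if spec.K > panel.n:
        raise ValueError(f"K={spec.K} exceeds the {panel.n} available participants")

    rng = np.random.default_rng(spec.seed)
    best: GbtmModel | None = None
    for start in range(spec.n_starts):
        resp = _initial_resp(panel, spec.K, start, rng)
        pi, beta, sigma, collapsed = _m_step(panel, resp, spec.shared_sigma)
        path: list[float] = []
        ll = -np.inf
        converged = False
        for it in range(spec.max_iter):
            new_ll, logpost, lse = _mixture_loglik(panel, pi, beta, sigma)
            path.append(new_ll)
            resp = np.exp(logpost - lse[:, None])
            pi, beta, sigma, step_collapsed = _m_step(panel, resp, spec.shared_sigma)
            collapsed = collapsed or step_collapsed
            if np.isfinite(ll) and abs(new_ll - ll) <= spec.tol * (abs(ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        final_ll, _, _ = _mixture_loglik(panel, pi, beta, sigma)
        path.append(final_ll)
        model = _finalize(
            panel, spec, pi, beta, sigma, final_ll, converged, collapsed, path
        )
        if best is None or (model.converged, model.loglik) > (best.converged, best.loglik):
            best = model
    return best


def _finalize(panel, spec, pi, beta, sigma, ll, converged, collapsed, path) -> GbtmModel:
    order_idx = np.argsort(beta[:, 0], kind="stable")  # canonical: ascending intercept
    pi = pi[order_idx]
    beta = beta[order_idx]
    sigma = np.asarray(sigma)
    if sigma.ndim == 1:
        sigma = sigma[order_idx]
    k = spec.K * (spec.order + 1) + (spec.K - 1) + (1 if spec.shared_sigma else spec.K)
    n_for_bic = panel.n if spec.bic_n == "participants" else panel.n_obs
    model = GbtmModel(
        pi=pi,
        beta=beta,
        sigma=sigma,
        shared_sigma=spec.shared_sigma,
        order=spec.order,
        loglik=ll,
        n_params=k,
        bic=ll - 0.5 * k * math.log(n_for_bic),
        converged=converged,
        n_participants=panel.n,
        n_observations=panel.n_obs,
        n_iter=len(path) - 1,
        loglik_path=path,
        collapsed=collapsed,
    )
    return model


def bic(model: GbtmModel) -> float:
    """BIC = loglik - 0.5 * n_params * ln(n_participants); larger is better."""
    if model.n_participants < 2:
        raise ValueError("BIC requires at least 2 participants")
    return model.loglik - 0.5 * model.n_params * math.log(model.n_participants)


def select_k(
    series: list[SpeedSeries],
    k_range,
    spec: GbtmSpec,
) -> tuple[GbtmModel, list[dict]]:
    """Fit every K in ``k_range`` (fresh seeded restarts per K) and pick the
    maximal-BIC model; ties break toward the smaller K.  A K whose fit raises
    is recorded in the table with its error and skipped."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    table: list[dict] = []
    best: GbtmModel | None = None
    for K in ks:
        kspec = GbtmSpec(
            K=K,
            order=spec.order,
            shared_sigma=spec.shared_sigma,
            n_starts=spec.n_starts,
            max_iter=spec.max_iter,
            tol=spec.tol,
            seed=(spec.seed * 1000003 + K) % (2**31),
            bic_n=spec.bic_n,
        )
        try:
            model = fit_em(series, kspec)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            table.append({"K": K, "error": str(exc)})
            continue
        table.append(
            {
                "K": K,
                "loglik": model.loglik,
                "n_params": model.n_params,
                "bic": model.bic,
                "converged": model.converged,
            }
        )
        if best is None or model.bic > best.bic:
            best = model
    if best is None:
        raise RuntimeError("every candidate K failed to fit")
    return best, table


def posteriors(model: GbtmModel, series: list[SpeedSeries]) -> PosteriorAssignment:
    """Bayes-rule group responsibilities and max-posterior hard labels
    (ties resolve to the lowest group index)."""
    panel = _Panel(series, model.order)
    _, logpost, lse = _mixture_loglik(panel, model.pi, model.beta, model.sigma)
    post = np.exp(logpost - lse[:, None])
    labels = np.argmax(post, axis=1)  # argmax takes the first (lowest) index on ties
    maxp = post[np.arange(panel.n), labels]
    avg = np.full(model.K, np.nan)
    for j in range(model.K):
        mask = labels == j
        if mask.any():
            avg[j] = float(maxp[mask].mean())
    return PosteriorAssignment(
        participant_ids=panel.ids,
        posterior=post,
        hard_label={pid: int(g) for pid, g in zip(panel.ids, labels)},
        avg_posterior=avg,
    )
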