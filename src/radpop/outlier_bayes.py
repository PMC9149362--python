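"""Bayesian FST outlier scan (BayeScan-style reversible-jump MCMC).

Observed ALT-allele counts per locus/population follow a beta-binomial
marginal: alt_ij ~ Binomial(tot_ij, p~_ij) with p~_ij ~ Beta(theta_ij p_i,
theta_ij (1 - p_i)), where theta_ij = 1/FST_ij - 1 and the locus-specific
FST decomposes on the logit scale as logit(FST_ij) = alpha_i delta_i +
beta_j.  beta_j captures the population's shared drift, alpha_i a
locus-specific (selection) effect that is present only when the indicator
delta_i is on.  A reversible-jump move flips delta_i, with alpha drawn
from its prior, so the acceptance ratio is the likelihood ratio times the
prior inclusion odds.  The posterior inclusion probability P_i and its
derived q-value drive the outlier decision (q <= 0.3 and P > 0.7 by
default).

Note logit(FST) = eta implies theta = exp(-eta), which keeps the whole
sampler in unconstrained space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit
from sklearn.base import BaseEstimator

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "BayesScanConfig",
    "BayesScanResult",
    "BayesFstScan",
    "allele_count_table",
    "bayescan_fit",
    "bayescan_qvalues",
    "bayescan_decide",
]


@dataclass
class BayesScanConfig:
    """Chain controls for the Bayesian scan.

    ``prior_odds`` is the prior ratio favoring the neutral model; the prior
    inclusion probability is 1/(1+prior_odds).  The chain defaults are
    desk-scale (far shorter than the original tool's).
    """

    prior_odds: float = 100.0
    n_burnin: int = 5000
    n_samples: int = 25000
    thin: int = 10
    pilot_rounds: int = 20
    pilot_length: int = 500
    step_p: float = 0.5
    step_alpha: float = 0.5
    step_beta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_odds <= 0:
            raise ValueError("prior_odds must be positive")
        for f in ("n_burnin", "n_samples", "thin"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def prior_inclusion(self) -> float:
        return 1.0 / (1.0 + self.prior_odds)


@dataclass
class BayesScanResult:
    P: np.ndarray  # posterior inclusion probability per locus
    alpha: np.ndarray  # posterior mean locus effect (0 if never included)
    fst: np.ndarray  # posterior mean FST per locus (averaged over pops)
    q: np.ndarray
    flags: np.ndarray
    beta: np.ndarray  # posterior mean per-population effect
    acceptance: dict[str, float]
    n_kept: int
    locus_ids: list[str] = field(default_factory=list)


def allele_count_table(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """ALT and total allele counts per locus x population (2 per genotyped
    diploid; missing genotypes reduce the totals)."""
    from .popgen import _pop_rows

    rows = _pop_rows(gm, pm)
    pops = list(rows)
    L = gm.n_loci
    alt = np.zeros((L, len(pops)))
    tot = np.zeros((L, len(pops)))
    for k, pop in enumerate(pops):
        calls = gm.calls[rows[pop]]
        present = calls != MISSING
        alt[:, k] = np.where(present, calls, 0).sum(axis=0)
        tot[:, k] = 2 * present.sum(axis=0)
    return alt, tot, pops


class BayesFstScan(BaseEstimator):
    """Reversible-jump MCMC scan for FST outlier loci.

    ``fit(alt, tot)`` takes (n_loci, n_pops) ALT and total allele counts.
    Fitted attributes: ``P_``, ``alpha_``, ``fst_``, ``q_``, ``flags_``,
    ``beta_``, ``acceptance_``.

    ``include_locus_effects=False`` fixes delta = 0 (pure drift model) and,
    combined with ``tie_betas=True``, reduces the model to a shared-FST
    posterior over (p_i, FST) used as a grid-integration oracle in tests.
    """

    def __init__(
        self,
        prior_odds: float = 100.0,
        n_burnin: int = 5000,
        n_samples: int = 25000,
        thin: int = 10,
        pilot_rounds: int = 20,
        pilot_length: int = 500,
        seed: int | None = None,
        q_max: float = 0.3,
        p_min: float = 0.7,
        beta_prior_mean: float = -1.0,
        beta_prior_sd: float = 1.8,
        alpha_prior_sd: float = 1.0,
        include_locus_effects: bool = True,
        tie_betas: bool = False,
    ):
        self.prior_odds = prior_odds
        self.n_burnin = n_burnin
        self.n_samples = n_samples
        self.thin = thin
        self.pilot_rounds = pilot_rounds
        self.pilot_length = pilot_length
        self.seed = seed
        self.q_max = q_max
        self.p_min = p_min
        self.beta_prior_mean = beta_prior_mean
        self.beta_prior_sd = beta_prior_sd
        self.alpha_prior_sd = alpha_prior_sd
        self.include_locus_effects = include_locus_effects
        self.tie_betas = tie_betas

    # -- likelihood ----------------------------------------------------

    @staticmethod
    def _loglik(alt, ref, p, eta):
        """Beta-binomial log likelihood per (locus, pop); binomial
        coefficients are constant and omitted."""
        theta = np.exp(-eta)
        a = theta * p[:, None]
        b = theta * (1.0 - p)[:, None]
        return betaln(alt + a, ref + b) - betaln(a, b)

    @staticmethod
    def _logjac(x):
        """log p(1-p) for p = expit(x): Jacobian of the uniform prior under
        the logit transform."""
        return -(np.logaddexp(0.0, x) + np.logaddexp(0.0, -x))

    def fit(self, alt, tot, y=None):
        if self.seed is None:
            raise ValueError("an explicit seed is required for the MCMC")
        alt = np.asarray(alt, dtype=float)
        tot = np.asarray(tot, dtype=float)
        if alt.shape != tot.shape or alt.ndim != 2:
            raise ValueError("alt and tot must be (n_loci, n_pops) arrays")
        if (alt > tot).any() or (alt < 0).any():
            raise ValueError("allele counts inconsistent (need 0 <= alt <= tot)")
        L, J = alt.shape
        if J < 2:
            raise ValueError("need at least 2 populations")
        ref = tot - alt
        rng = np.random.default_rng(self.seed)
        pi = 1.0 / (1.0 + self.prior_odds)
        log_prior_odds_in = np.log(pi) - np.log1p(-pi)

        # initial state: p at the pooled frequency, no locus effects,
        # beta at its prior mean
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = np.where(tot.sum(1) > 0, alt.sum(1) / np.maximum(tot.sum(1), 1), 0.5)
        p = np.clip(p0, 0.01, 0.99)
        x = np.log(p / (1 - p))
        alpha = np.zeros(L)
        delta = np.zeros(L, dtype=bool)
        n_beta = 1 if self.tie_betas else J
        beta = np.full(n_beta, self.beta_prior_mean)

        step_p = np.full(L, 0.8)
        step_a = np.full(L, 0.8)
        step_b = np.full(n_beta, 0.3)

        def expand_beta(b):
            return np.broadcast_to(b, (J,)) if self.tie_betas else b

        def eta_of(alpha, delta, beta):
            return (alpha * delta)[:, None] + expand_beta(beta)[None, :]

        ll = self._loglik(alt, ref, p, eta_of(alpha, delta, beta))

        # per-locus RJ proposal for alpha, learned during the pilot phase
        # (prior draws almost never reach the large effects real outliers
        # need, so births would be hopeless without this)
        rj_mu = np.zeros(L)
        rj_sd = np.full(L, self.alpha_prior_sd)

        acc = {"p": 0, "alpha": 0, "rj": 0, "beta": 0}
        tries = {"p": 0, "alpha": 0, "rj": 0, "beta": 0}

        sum_delta = np.zeros(L)
        sum_alpha = np.zeros(L)
        n_alpha = np.zeros(L)
        sum_fst = np.zeros(L)
        sum_beta = np.zeros(n_beta)
        n_kept = 0

        def sweep(n_iter, tune_every=0, record=False, thin=1, rj=True,
                  collect_alpha=None):
            nonlocal p, x, alpha, delta, beta, ll, n_kept
            acc_round = {k: np.zeros_like(v, dtype=float) for k, v in
                         {"p": step_p, "alpha": step_a, "beta": step_b}.items()}
            tries_alpha = np.zeros(L)
            for it in range(n_iter):
                # ---- allele frequencies p (logit random walk)
                x_new = x + step_p * rng.standard_normal(L)
                p_new = expit(x_new)
                ll_new = self._loglik(alt, ref, p_new, eta_of(alpha, delta, beta))
                logacc = (ll_new - ll).sum(1) + self._logjac(x_new) - self._logjac(x)
                ok = np.log(rng.random(L)) < logacc
                x = np.where(ok, x_new, x)
                p = np.where(ok, p_new, p)
                ll[ok] = ll_new[ok]
                acc["p"] += int(ok.sum()); tries["p"] += L
                acc_round["p"] += ok

                # ---- locus effects alpha (only where included)
                if self.include_locus_effects and delta.any():
                    a_new = alpha + step_a * rng.standard_normal(L)
                    ll_new = self._loglik(alt, ref, p, eta_of(a_new, delta, beta))
                    logacc = (ll_new - ll).sum(1) + (alpha**2 - a_new**2) / (
                        2 * self.alpha_prior_sd**2
                    )
                    ok = delta & (np.log(rng.random(L)) < logacc)
                    alpha = np.where(ok, a_new, alpha)
                    ll[ok] = ll_new[ok]
                    acc["alpha"] += int(ok.sum()); tries["alpha"] += int(delta.sum())
                    acc_round["alpha"] += ok
                    tries_alpha += delta

                # ---- reversible-jump flip of delta; births draw alpha from
                # the pilot-learned per-locus proposal, with the Hastings
                # correction prior(alpha)/proposal(alpha)
                if self.include_locus_effects and rj:
                    d_new = ~delta
                    a_prop = np.where(
                        d_new, rj_mu + rj_sd * rng.standard_normal(L), alpha
                    )
                    a_eval = np.where(d_new, a_prop, alpha)
                    ll_new = self._loglik(alt, ref, p, eta_of(a_prop, d_new, beta))
                    log_prior = (
                        -0.5 * (a_eval / self.alpha_prior_sd) ** 2
                        - np.log(self.alpha_prior_sd)
                    )
                    log_prop = (
                        -0.5 * ((a_eval - rj_mu) / rj_sd) ** 2 - np.log(rj_sd)
                    )
                    correction = np.where(
                        d_new,
                        log_prior - log_prop + log_prior_odds_in,
                        log_prop - log_prior - log_prior_odds_in,
                    )
                    logacc = (ll_new - ll).sum(1) + correction
                    ok = np.log(rng.random(L)) < logacc
                    delta = np.where(ok, d_new, delta)
                    alpha = np.where(ok, np.where(d_new, a_prop, 0.0), alpha)
                    ll[ok] = ll_new[ok]
                    acc["rj"] += int(ok.sum()); tries["rj"] += L

                # ---- population effects beta
                for j in range(n_beta):
                    b_new = beta.copy()
                    b_new[j] = beta[j] + step_b[j] * rng.standard_normal()
                    if self.tie_betas:
                        cols = slice(None)
                    else:
                        cols = slice(j, j + 1)
                    eta_col = (alpha * delta)[:, None] + expand_beta(b_new)[None, cols]
                    ll_col = self._loglik(
                        alt[:, cols], ref[:, cols], p, eta_col
                    )
                    dprior = (
                        (beta[j] - self.beta_prior_mean) ** 2
                        - (b_new[j] - self.beta_prior_mean) ** 2
                    ) / (2 * self.beta_prior_sd**2)
                    logacc = (ll_col - ll[:, cols]).sum() + dprior
                    if np.log(rng.random()) < logacc:
                        beta = b_new
                        ll[:, cols] = ll_col
                        acc["beta"] += 1
                        acc_round["beta"][j] += 1
                    tries["beta"] += 1

                if tune_every and (it + 1) % tune_every == 0:
                    rate_p = acc_round["p"] / tune_every
                    step_p[rate_p < 0.25] *= 0.8
                    step_p[rate_p > 0.45] *= 1.25
                    np.clip(step_p, 1e-3, 10.0, out=step_p)
                    acc_round["p"][:] = 0.0
                    # alpha steps: only tune loci actually included this round
                    seen = tries_alpha > 0
                    rate_a = acc_round["alpha"] / np.maximum(tries_alpha, 1)
                    step_a[seen & (rate_a < 0.25)] *= 0.8
                    step_a[seen & (rate_a > 0.45)] *= 1.25
                    np.clip(step_a, 1e-3, 10.0, out=step_a)
                    acc_round["alpha"][:] = 0.0
                    tries_alpha[:] = 0.0
                    rate_b = acc_round["beta"] / tune_every
                    step_b[rate_b < 0.25] *= 0.8
                    step_b[rate_b > 0.45] *= 1.25
                    np.clip(step_b, 1e-3, 10.0, out=step_b)
                    acc_round["beta"][:] = 0.0

                if collect_alpha is not None and it >= n_iter // 2:
                    collect_alpha[0] += alpha
                    collect_alpha[1] += alpha**2
                    collect_alpha[2] += 1

                if record and (it + 1) % thin == 0:
                    sum_delta[:] += delta
                    sum_alpha[:] += np.where(delta, alpha, 0.0)
                    n_alpha[:] += delta
                    sum_fst[:] += expit(eta_of(alpha, delta, beta)).mean(axis=1)
                    sum_beta[:] += beta
                    n_kept += 1

        # Pilot phase: tune proposal step sizes and learn the RJ proposal.
        # All loci are forced in so every alpha gets conditional-posterior
        # samples; afterwards the state is reset to the neutral model.
        if self.pilot_rounds > 0:
            if self.include_locus_effects:
                delta[:] = True
                ll = self._loglik(alt, ref, p, eta_of(alpha, delta, beta))
                collected = [np.zeros(L), np.zeros(L), 0]
                sweep(self.pilot_rounds * self.pilot_length,
                      tune_every=self.pilot_length, rj=False,
                      collect_alpha=collected)
                n_coll = max(collected[2], 1)
                rj_mu = collected[0] / n_coll
                var = collected[1] / n_coll - rj_mu**2
                rj_sd = np.sqrt(np.clip(var, 0.04, 9.0))
                delta[:] = False
                alpha[:] = 0.0
            else:
                sweep(self.pilot_rounds * self.pilot_length,
                      tune_every=self.pilot_length, rj=False)
            ll = self._loglik(alt, ref, p, eta_of(alpha, delta, beta))
            acc.update({k: 0 for k in acc})
            tries.update({k: 0 for k in tries})
        sweep(self.n_burnin)
        sweep(self.n_samples, record=True, thin=self.thin)

        rates = {
            k: (acc[k] / tries[k] if tries[k] else float("nan")) for k in acc
        }
        for k, r in rates.items():
            # RJ flips are *expected* to be rejected at most neutral loci
            if k != "rj" and np.isfinite(r) and r < 0.05 and tries[k] > 0:
                warnings.warn(
                    f"low MCMC acceptance rate for block {k!r} ({r:.3f}); "
                    f"consider smaller proposal step sizes or longer pilot tuning"
                )

        P = sum_delta / n_kept
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha_mean = np.where(n_alpha > 0, sum_alpha / np.maximum(n_alpha, 1), 0.0)
        q = bayescan_qvalues(P)
        self.P_ = P
        self.alpha_ = alpha_mean
        self.fst_ = sum_fst / n_kept
        self.q_ = q
        self.flags_ = bayescan_decide(P, q, self.q_max, self.p_min)
        self.beta_ = sum_beta / n_kept
        self.acceptance_ = rates
        self.n_kept_ = n_kept
        return self

    def predict(self, X=None):
        return self.flags_


def bayescan_fit(
    alt: np.ndarray,
    tot: np.ndarray,
    cfg: BayesScanConfig | None = None,
    locus_ids: list[str] | None = None,
) -> BayesScanResult:
    """Run the Bayesian scan on (n_loci, n_pops) allele-count arrays."""
    cfg = cfg or BayesScanConfig()
    model = BayesFstScan(
        prior_odds=cfg.prior_odds,
        n_burnin=cfg.n_burnin,
        n_samples=cfg.n_samples,
        thin=cfg.thin,
        pilot_rounds=cfg.pilot_rounds,
        pilot_length=cfg.pilot_length,
        seed=cfg.seed,
    ).fit(alt, tot)
    return BayesScanResult(
        P=model.P_,
        alpha=model.alpha_,
        fst=model.fst_,
        q=model.q_,
        flags=model.flags_,
        beta=model.beta_,
        acceptance=model.acceptance_,
        n_kept=model.n_kept_,
        locus_ids=list(locus_ids or []),
    )


def bayescan_qvalues(P: np.ndarray) -> np.ndarray:
    """q-value per locus: rank by decreasing P; q at rank k is the running
    mean of (1 - P) over the top-k loci."""
    P = np.asarray(P, dtype=float)
    order = np.argsort(-P, kind="stable")
    running = np.cumsum(1.0 - P[order]) / np.arange(1, len(P) + 1)
    q = np.empty_like(running)
    q[order] = running
    return q


def bayescan_decide(
    P: np.ndarray, q: np.ndarray, q_max: float = 0.3, p_min: float = 0.7
) -> np.ndarray:
    """Outlier iff q <= q_max (inclusive) and P > p_min (strict)."""
    return (np.asarray(q) <= q_max) & (np.asarray(P) > p_min)
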