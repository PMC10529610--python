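"""Random-effects Bayesian model selection (BMS).

Treats the generative model as a random variable across subjects with
unknown population frequencies r ~ Dirichlet(alpha).  A variational
scheme iterates subject-wise model responsibilities (softmax of the
log-model evidence plus digamma terms) against the Dirichlet
concentrations.  Exceedance probabilities (EP) — the posterior
probability that each model is the most frequent — come from Monte-Carlo
draws of the posterior Dirichlet (exact Beta comparison when K = 2).
The Bayes omnibus risk (BOR) is the posterior probability that all
models are equally frequent, from the free-energy comparison of the
random-effects model against that null; protected exceedance
probabilities mix the two:

    PXP_k = EP_k * (1 - BOR) + BOR / K
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BMSResult", "rfx_bms", "model_recovery"]


@dataclass
class BMSResult:
    models: list[str]
    alpha: np.ndarray           # Dirichlet posterior concentrations
    frequencies: np.ndarray     # expected model frequencies r
    ep: np.ndarray              # exceedance probabilities
    bor: float                  # Bayes omnibus risk
    pxp: np.ndarray             # protected exceedance probabilities
    responsibilities: np.ndarray = field(repr=False, default=None)  # type: ignore
    seed: int = 0
    n_samples: int = 0

    def family_pxp(self, members) -> float:
        """Summed PXP of a family of models (PXP sums to 1 over models,
        so family protection is the sum over members)."""
        idx = [self.models.index(m) for m in members]
        return float(np.sum(self.pxp[idx]))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "model": self.models, "alpha": self.alpha,
            "frequency": self.frequencies, "ep": self.ep,
            "pxp": self.pxp, "bor": self.bor,
        })


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray,
                  tol: float = 1e-6, max_iter: int = 10000
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Variational posterior (alpha, responsibilities) for the
    random-effects model."""
    alpha = alpha0.copy()
    for _ in range(max_iter):
        w = lme + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        g = np.exp(w)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def _free_energy_rfx(lme: np.ndarray, alpha0: np.ndarray,
                     alpha: np.ndarray, g: np.ndarray) -> float:
    """Variational free energy of the random-effects model."""
    dig = digamma(alpha) - digamma(alpha.sum())
    elbo = float(np.sum(g * (lme + dig)))
    # entropy of q(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    elbo += float(ent)
    # KL-related Dirichlet terms: E[log p(r)] - E[log q(r)]
    elbo += float(
        gammaln(alpha0.sum()) - np.sum(gammaln(alpha0))
        + np.sum((alpha0 - 1.0) * dig)
    )
    elbo -= float(
        gammaln(alpha.sum()) - np.sum(gammaln(alpha))
        + np.sum((alpha - 1.0) * dig)
    )
    return elbo


def _free_energy_null(lme: np.ndarray) -> float:
    """Log evidence of the null: every subject drawn from a uniform
    fixed frequency profile r = 1/K."""
    n, k = lme.shape
    return float(np.sum(logsumexp(lme - np.log(k), axis=1)))


def rfx_bms(lme, models=None, alpha0: float = 1.0, seed: int = 0,
            n_samples: int = 100000, force_mc: bool = False) -> BMSResult:
    """Random-effects BMS over a subjects x models LME matrix.

    ``alpha0`` is the symmetric Dirichlet prior concentration (1 =
    uniform).  EPs use ``n_samples`` Monte-Carlo Dirichlet draws except
    for a symmetric posterior (uniform by exchangeability) and for
    K = 2 (exact Beta comparison); ``force_mc`` disables both shortcuts
    so the sampler can be validated against the closed forms.
    """
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("LME matrix must be subjects x (>= 2) models")
    if not np.all(np.isfinite(lme)):
        bad = np.argwhere(~np.isfinite(lme))[0]
        raise ValueError(
            f"non-finite LME for subject {bad[0]}, model {bad[1]}")
    n, k = lme.shape
    if models is None:
        models = [f"M{i + 1}" for i in range(k)]
    a0 = np.full(k, float(alpha0))

    alpha, g = _vb_dirichlet(lme, a0)
    freq = alpha / alpha.sum()

    mc_used = False
    if not force_mc and np.allclose(alpha, alpha[0], rtol=0, atol=1e-12):
        # exchangeable posterior: every model is equally likely to be
        # the most frequent
        ep = np.full(k, 1.0 / k)
    elif not force_mc and k == 2:
        # exact: EP1 = P(r1 > 0.5), r1 ~ Beta(alpha1, alpha2)
        from scipy.stats import beta as beta_dist
        ep1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        ep = np.array([ep1, 1.0 - ep1])
    else:
        mc_used = True
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_samples)
        winners = np.argmax(draws, axis=1)
        ep = np.bincount(winners, minlength=k) / n_samples

    f_rfx = _free_energy_rfx(lme, a0, alpha, g)
    f_null = _free_energy_null(lme)
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))
    pxp = ep * (1.0 - bor) + bor / k
    return BMSResult(
        models=list(models), alpha=alpha, frequencies=freq, ep=ep,
        bor=bor, pxp=pxp, responsibilities=g, seed=seed,
        n_samples=n_samples if mc_used else 0,
    )


def family_bms(lme, models, families: dict[str, list[str]],
               alpha0: float = 1.0, seed: int = 0,
               n_samples: int = 100000) -> BMSResult:
    """Family-level random-effects BMS.

    Aggregates each family's evidence per subject under a uniform
    within-family prior — ``L_fam = logsumexp(members) - log(m)`` — and
    runs the random-effects scheme over families.  This protects the
    comparison against dilution when a family contains near-equivalent
    members (e.g. two HGF variants that short series cannot separate).
    """
    lme = np.asarray(lme, dtype=float)
    models = list(models)
    cols = {}
    seen: list[str] = []
    for fam, members in families.items():
        idx = [models.index(m) for m in members]
        seen.extend(members)
        cols[fam] = logsumexp(lme[:, idx], axis=1) - np.log(len(idx))
    if sorted(seen) != sorted(models):
        raise ValueError("families must partition the model list")
    fam_lme = np.column_stack([cols[f] for f in families])
    return rfx_bms(fam_lme, models=list(families), alpha0=alpha0,
                   seed=seed, n_samples=n_samples)


def model_recovery(model_names, n_subjects: int, designs, seed: int = 0,
                   true_ranges: dict | None = None, n_restarts: int = 4,
                   priors: dict | None = None,
                   n_repetitions: int = 1):
    """Confusion matrix of PXP winners: for each generating model,
    simulate a cohort, fit all candidates, run BMS, and record which
    model wins by PXP.  Returns (matrix, row_models, col_models); rows
    sum to ``n_repetitions``.  Fit failures are excluded subjects."""
    import pandas as pd

    from sensolearn.agents import simulate_agent
    from sensolearn.inversion import map_fit
    from sensolearn.models import get_model

    rng = np.random.default_rng(seed)
    mat = np.zeros((len(model_names), len(model_names)), dtype=int)
    for rep in range(n_repetitions):
        for gi, gen in enumerate(model_names):
            spec = get_model(gen)
            lmes = []
            for s in range(n_subjects):
                design = designs[s % len(designs)]
                free = spec.free_params
                tr = true_ranges or {}
                while True:
                    params_t = {
                        p.name: rng.uniform(*tr.get(
                            p.name,
                            (p.prior_mean - 1.0, p.prior_mean + 1.0)))
                        for p in free
                    }
                    native = {p.name: p.to_native(params_t[p.name])
                              for p in free}
                    zeta = native.pop("zeta")
                    try:
                        agent = simulate_agent(
                            design, gen, native, {"zeta": zeta},
                            seed=int(rng.integers(2**31 - 1)))
                        break
                    except Exception:
                        continue
                row = []
                for cand in model_names:
                    fit = map_fit(
                        agent.u, agent.y, cand,
                        priors=None if priors is None else priors.get(cand),
                        n_restarts=n_restarts,
                        seed=int(rng.integers(2**31 - 1)))
                    row.append(fit.lme)
                if np.all(np.isfinite(row)):
                    lmes.append(row)
            result = rfx_bms(np.array(lmes), models=list(model_names),
                             seed=int(rng.integers(2**31 - 1)))
            mat[gi, int(np.argmax(result.pxp))] += 1
    return pd.DataFrame(mat, index=list(model_names),
                        columns=list(model_names))
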