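"""Bayesian multi-response (phylogenetic) mixed models over strain traits.

The model for observation *i* of trait *t* on symbiont strain *w* is

    y_twi = beta_t + u_s:tw [+ u_p:tw] + e_twi

with a strain random effect ``u_s`` (trait covariance ``V_s``, independent
across strains), an optional phylogenetic random effect ``u_p`` (covariance
``V_p (x) A`` with ``A`` the shared-ancestry matrix, the Brownian-motion
structure), and per-trait residual variances.  Traits are measured on
different biological replicates, so residuals are independent across traits
and missing (strain, trait) cells simply drop out of the likelihood.

Estimation is a blocked Gibbs sampler with conjugate updates: the fixed
effects and all stacked random effects are drawn jointly from their
Gaussian full conditional; ``V_s`` and ``V_p`` from inverse-Wishart full
conditionals (the phylogenetic one weighted by ``A^-1``); residual
variances from scaled inverse-chi-square conditionals.  Three prior
families are supported for the covariances — parameter-expanded (redundant
per-trait working scale parameters with a Gaussian working prior, giving a
half-t-like marginal on effect standard deviations), inverse-Wishart, and
flat — so prior sensitivity can be checked.

Genetic correlations ``r_g = sigma_t1t2 / sqrt(sigma2_t1 sigma2_t2)`` are
computed per posterior draw from the chosen component and summarized by the
posterior mean and 95% highest-posterior-density interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .phylo import SharedAncestryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "STUDY_MODELS",
    "ModelSpec",
    "PosteriorDraws",
    "GeneticCorrelation",
    "fit_multiresponse",
    "genetic_correlation",
    "hpd_interval",
    "convergence_report",
    "component_regression_compare",
]


# The six trait combinations of the motivating study design: protection
# (per-vial -ln hazard ratio) after each challenge, symbiont density, viral
# titers, and host immune / methyltransferase gene expression per virus.
STUDY_MODELS: dict[str, tuple[str, ...]] = {
    "model1": ("survival_DCV", "survival_FHV", "survival_Ringer", "density"),
    "model2": ("titer_DCV", "titer_FHV", "density"),
    "model3": ("survival_DCV", "titer_DCV"),
    "model4": ("survival_FHV", "titer_FHV"),
    "model5": ("survival_DCV", "Drosomycin_DCV", "Diptericin_DCV", "Dnmt2_DCV"),
    "model6": ("survival_FHV", "Drosomycin_FHV", "Diptericin_FHV", "Dnmt2_FHV"),
}


@dataclass
class ModelSpec:
    """Traits, random-effect structure, priors and MCMC schedule.

    The default schedule (50k iterations, 10k burn-in, thin 10) is scaled
    for desk use; the long production schedule (13M / 3M) is available by
    overriding ``iterations`` / ``burn_in``.
    """

    traits: tuple[str, ...]
    include_strain_effect: bool = True
    include_phylo_effect: bool = False
    A: SharedAncestryMatrix | None = None
    prior: str = "parameter-expanded"        # | "inverse-wishart" | "flat"
    iw_df_offset: float = 1.0                # IW df = n_traits + offset
    iw_scale: float = 0.01                   # IW scale matrix = iw_scale * I
    px_alpha_scale: float = 1.0              # sd of the Gaussian working-scale prior
    fixed_prior_variance: float = 1e10       # N(0, 1e10) on trait intercepts
    residual_prior_nu: float = 0.002         # scaled-inv-chi2 (weak)
    residual_prior_s2: float = 1.0
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    fixed_covariance: dict = field(default_factory=dict)  # {"strain": matrix} to fix
    a_jitter: float = 1e-8

    def validate(self) -> None:
        if not (self.include_strain_effect or self.include_phylo_effect):
            raise ValueError("at least one of strain / phylogenetic effects must be on")
        if self.include_phylo_effect and self.A is None:
            raise ValueError("phylogenetic effect requires a shared-ancestry matrix A")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior not in ("parameter-expanded", "inverse-wishart", "flat"):
            raise ValueError(f"unknown prior family {self.prior!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples of the multi-response model parameters."""

    traits: list[str]
    strains: list[str]
    beta: np.ndarray                  # (ndraws, T)
    V_s: np.ndarray | None            # (ndraws, T, T)
    V_p: np.ndarray | None
    residual_var: np.ndarray          # (ndraws, T)
    u_s_mean: pd.DataFrame | None = None   # posterior-mean strain effects
    u_p_mean: pd.DataFrame | None = None
    pd_rejections: int = 0
    spec: ModelSpec | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def component(self, name: str) -> np.ndarray:
        if name == "strain":
            V = self.V_s
        elif name in ("phylo", "phylogenetic"):
            V = self.V_p
        elif name == "combined":
            if self.V_s is None or self.V_p is None:
                raise KeyError("combined component needs both strain and phylo effects")
            return self.V_s + self.V_p
        else:
            raise KeyError(f"unknown component {name!r}")
        if V is None:
            raise KeyError(f"component {name!r} was not fitted")
        return V

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Flat name -> chain mapping for diagnostics."""
        out = {}
        for t, name in enumerate(self.traits):
            out[f"beta[{name}]"] = self.beta[:, t]
            out[f"resid_var[{name}]"] = self.residual_var[:, t]
        for label, V in (("V_s", self.V_s), ("V_p", self.V_p)):
            if V is None:
                continue
            for i, ti in enumerate(self.traits):
                for j, tj in enumerate(self.traits[: i + 1]):
                    out[f"{label}[{ti},{tj}]"] = V[:, i, j]
        return out


@dataclass
class GeneticCorrelation:
    trait_pair: tuple[str, str]
    component: str
    mean: float
    hpd_lower: float
    hpd_upper: float
    draws: np.ndarray | None = None


# ---------------------------------------------------------------------------

def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def _sample_iw(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng).reshape(scale.shape)


class _Component:
    """One random-effect component (strain or phylogenetic) in the sampler."""

    def __init__(self, name, S, T, Kinv, prior, spec, rng, fixed_V=None):
        self.name = name
        self.S, self.T = S, T
        self.Kinv = Kinv            # S x S between-strain precision (I or A^-1)
        self.prior = prior
        self.spec = spec
        self.fixed_V = None if fixed_V is None else np.atleast_2d(np.asarray(fixed_V, float))
        self.eta = np.zeros((S, T))           # working-scale effects
        self.alpha = np.ones(T)               # PX working scales (1 if not PX)
        self.Vwork = np.eye(T)                # working covariance (= V unless PX)
        if self.fixed_V is not None:
            self.Vwork = self.fixed_V.copy()
        self.rejections = 0

    @property
    def u(self) -> np.ndarray:
        return self.eta * self.alpha

    @property
    def V(self) -> np.ndarray:
        if self.fixed_V is not None:
            return self.fixed_V
        D = np.diag(self.alpha)
        return D @ self.Vwork @ D

    def update_V(self, rng):
        if self.fixed_V is not None:
            return
        T, S = self.T, self.S
        quad = self.eta.T @ self.Kinv @ self.eta
        if self.prior == "flat":
            df = S - T - 1
            if df <= T - 1:
                raise ValueError(
                    f"flat covariance prior needs more strains than 2*traits "
                    f"(S={S}, T={T})"
                )
            scale = quad
        else:
            # PX uses an identity-scale working prior; plain IW uses spec scale
            if self.prior == "parameter-expanded":
                nu0, S0 = T + 1.0, np.eye(T)
            else:
                nu0 = T + self.spec.iw_df_offset
                S0 = self.spec.iw_scale * np.eye(T)
            df = nu0 + S
            scale = S0 + quad
        scale = 0.5 * (scale + scale.T)
        for _ in range(20):
            V = _sample_iw(rng, df, scale)
            V = 0.5 * (V + V.T)
            if _is_pd(V):
                self.Vwork = V
                return
            self.rejections += 1
        raise FloatingPointError(f"could not draw a PD covariance for {self.name}")


def fit_multiresponse(table: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Run the blocked Gibbs sampler on a long trait table.

    ``table`` needs columns ``strain``, ``trait`` and ``value`` (one trait
    per row; replicates are simply repeated rows).  When the phylogenetic
    effect is on, every strain in the table must appear in ``spec.A``; a
    singular ``A`` (zero-divergence tips) is handled by adding a logged
    diagonal jitter before inversion.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    traits = list(spec.traits)
    T = len(traits)
    tab = table[table["trait"].isin(traits)].reset_index(drop=True)
    if not np.isfinite(tab["value"]).all():
        raise ValueError("trait values must be finite")

    if spec.include_phylo_effect:
        A = spec.A
        missing = set(tab["strain"]) - set(A.labels)
        if missing:
            raise ValueError(f"strains absent from A: {sorted(missing)}")
        strains = list(A.labels)
        Amat = A.A.copy()
        try:
            Ainv = np.linalg.inv(Amat)
            if not _is_pd(Amat):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            bad = getattr(A, "degenerate_pairs", [])
            logger.warning(
                "A is singular (offending tips: %s); adding %.1e jitter",
                bad or "unknown", spec.a_jitter,
            )
            Amat = Amat + spec.a_jitter * np.eye(len(strains))
            Ainv = np.linalg.inv(Amat)
    else:
        strains = sorted(tab["strain"].unique())
        Ainv = None
    S = len(strains)
    if S < 2:
        raise ValueError("need >= 2 strains")
    if spec.include_strain_effect and spec.include_phylo_effect and S < 30:
        logger.warning(
            "strain and phylogenetic effects are weakly identified with only "
            "%d strains; consider a phylogeny-only model", S,
        )

    t_of = {t: i for i, t in enumerate(traits)}
    w_of = {s: i for i, s in enumerate(strains)}
    row_t = tab["trait"].map(t_of).to_numpy()
    row_w = tab["strain"].map(w_of).to_numpy()
    row_y = tab["value"].to_numpy(dtype=float)
    n_t = np.bincount(row_t, minlength=T).astype(float)
    if (n_t == 0).any():
        missing = [traits[i] for i in np.where(n_t == 0)[0]]
        raise ValueError(f"no observations for trait(s) {missing}")

    components: list[_Component] = []
    if spec.include_strain_effect:
        components.append(_Component(
            "strain", S, T, np.eye(S), spec.prior, spec, rng,
            fixed_V=spec.fixed_covariance.get("strain"),
        ))
    if spec.include_phylo_effect:
        components.append(_Component(
            "phylo", S, T, Ainv, spec.prior, spec, rng,
            fixed_V=spec.fixed_covariance.get("phylo"),
        ))
    use_px = spec.prior == "parameter-expanded" and any(c.fixed_V is None for c in components)

    # ---- index bookkeeping for the joint Gaussian location update --------
    # theta = [beta (T)] + [eta_c (S*T, strain-major) per component]
    D = T + len(components) * S * T
    offs = [T + k * S * T for k in range(len(components))]

    cells = tab.groupby([pd.Series(row_w, name="w"), pd.Series(row_t, name="t")])["value"]
    cell_counts = cells.count()
    cell_idx = np.array(list(cell_counts.index), dtype=int)       # (C, 2)
    cell_w, cell_t = cell_idx[:, 0], cell_idx[:, 1]
    cell_n = cell_counts.to_numpy(dtype=float)
    cell_sum = cells.sum().to_numpy(dtype=float)

    # active parameter indices per cell: beta_t plus eta(w,t) per component
    act = [cell_t] + [off + cell_w * T + cell_t for off in offs]
    pair_i, pair_j, pair_a, pair_b = [], [], [], []   # a,b: which active slot
    for a in range(len(act)):
        for b in range(len(act)):
            pair_i.append(act[a])
            pair_j.append(act[b])
            pair_a.append(np.full(len(cell_n), a))
            pair_b.append(np.full(len(cell_n), b))
    pair_i = np.concatenate(pair_i)
    pair_j = np.concatenate(pair_j)
    pair_a = np.concatenate(pair_a)
    pair_b = np.concatenate(pair_b)
    pair_cell = np.tile(np.arange(len(cell_n)), len(act) ** 2)
    rhs_idx = np.concatenate(act)
    rhs_cell = np.tile(np.arange(len(cell_n)), len(act))
    rhs_slot = np.concatenate([np.full(len(cell_n), a) for a in range(len(act))])

    resid_var = np.ones(T)
    beta = np.zeros(T)

    n_keep = (spec.iterations - spec.burn_in) // spec.thin
    out_beta = np.empty((n_keep, T))
    out_res = np.empty((n_keep, T))
    out_V = {c.name: np.empty((n_keep, T, T)) for c in components}
    u_s_acc = {c.name: np.zeros((S, T)) for c in components}
    keep = 0

    prior_prec_beta = 1.0 / spec.fixed_prior_variance
    nu0, s20 = spec.residual_prior_nu, spec.residual_prior_s2

    for it in range(spec.iterations):
        # -- joint location update ------------------------------------------
        # column scales: 1 for beta, alpha_c[t] for component columns
        slot_scale = [np.ones(len(cell_n))] + [c.alpha[cell_t] for c in components]
        wgt = 1.0 / resid_var[cell_t]
        Prec = np.zeros((D, D))
        Prec[np.arange(T), np.arange(T)] = prior_prec_beta
        for k, c in enumerate(components):
            Vwi = np.linalg.inv(c.Vwork)
            block = np.kron(c.Kinv, Vwi)
            sl = slice(offs[k], offs[k] + S * T)
            Prec[sl, sl] += block
        vals = (cell_n * wgt)[pair_cell]
        sa = np.stack(slot_scale)          # (n_slots, C)
        vals = vals * sa[pair_a, pair_cell] * sa[pair_b, pair_cell]
        np.add.at(Prec, (pair_i, pair_j), vals)
        rhs = np.zeros(D)
        rvals = (cell_sum * wgt)[rhs_cell] * sa[rhs_slot, rhs_cell]
        np.add.at(rhs, rhs_idx, rvals)

        cF, low = linalg.cho_factor(Prec, lower=True, check_finite=False)
        mu = linalg.cho_solve((cF, low), rhs, check_finite=False)
        z = rng.standard_normal(D)
        theta = mu + linalg.solve_triangular(cF, z, trans="T", lower=True,
                                             check_finite=False)
        beta = theta[:T]
        for k, c in enumerate(components):
            c.eta = theta[offs[k]:offs[k] + S * T].reshape(S, T)

        # -- PX working-scale update ----------------------------------------
        if use_px:
            nC = len(components)
            Xa = np.zeros((len(cell_n), nC))
            for k, c in enumerate(components):
                Xa[:, k] = c.eta[cell_w, cell_t]
            prec_a = np.zeros((nC * T, nC * T))
            rhs_a = np.zeros(nC * T)
            resid_cell = cell_sum - cell_n * beta[cell_t]
            for k1 in range(nC):
                np.add.at(rhs_a, k1 * T + cell_t, wgt * Xa[:, k1] * resid_cell)
                for k2 in range(nC):
                    np.add.at(prec_a, (k1 * T + cell_t, k2 * T + cell_t),
                              wgt * cell_n * Xa[:, k1] * Xa[:, k2])
            prec_a[np.arange(nC * T), np.arange(nC * T)] += 1.0 / spec.px_alpha_scale**2
            cFa, lowa = linalg.cho_factor(prec_a, lower=True, check_finite=False)
            mua = linalg.cho_solve((cFa, lowa), rhs_a, check_finite=False)
            alpha_all = mua + linalg.solve_triangular(
                cFa, rng.standard_normal(nC * T), trans="T", lower=True,
                check_finite=False)
            for k, c in enumerate(components):
                if c.fixed_V is None:
                    c.alpha = alpha_all[k * T:(k + 1) * T]

        # -- covariance and residual updates --------------------------------
        for c in components:
            c.update_V(rng)
        fitted = beta[row_t]
        for c in components:
            fitted = fitted + c.u[row_w, row_t]
        res = row_y - fitted
        sse = np.bincount(row_t, weights=res**2, minlength=T)
        df = nu0 + n_t
        resid_var = (nu0 * s20 + sse) / rng.chisquare(df)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and keep < n_keep:
            out_beta[keep] = beta
            out_res[keep] = resid_var
            for c in components:
                out_V[c.name][keep] = c.V
                u_s_acc[c.name] += c.u
            keep += 1

    rej = sum(c.rejections for c in components)
    if rej:
        logger.info("resampled %d non-PD covariance draw(s)", rej)
    names = [c.name for c in components]
    return PosteriorDraws(
        traits=traits,
        strains=strains,
        beta=out_beta[:keep],
        V_s=out_V["strain"][:keep] if "strain" in names else None,
        V_p=out_V["phylo"][:keep] if "phylo" in names else None,
        residual_var=out_res[:keep],
        u_s_mean=(pd.DataFrame(u_s_acc["strain"] / max(keep, 1), index=strains,
                               columns=traits) if "strain" in names else None),
        u_p_mean=(pd.DataFrame(u_s_acc["phylo"] / max(keep, 1), index=strains,
                               columns=traits) if "phylo" in names else None),
        pd_rejections=rej,
        spec=spec,
    )


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally short windows break toward the lower window start.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HPD interval, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))     # argmin returns the first (lowest) start
    return float(x[i]), float(x[i + m - 1])


def genetic_correlation(
    draws: PosteriorDraws, t1: str, t2: str, component: str = "strain",
    mass: float = 0.95,
) -> GeneticCorrelation:
    """Posterior genetic correlation between two traits from one component."""
    traits = draws.traits
    for t in (t1, t2):
        if t not in traits:
            raise KeyError(f"trait {t!r} not in fitted traits {traits}")
    V = draws.component(component)
    i, j = traits.index(t1), traits.index(t2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = V[:, i, j] / np.sqrt(V[:, i, i] * V[:, j, j])
    r = r[np.isfinite(r)]
    lo, hi = hpd_interval(r, mass) if r.size >= 100 else (float(np.min(r)), float(np.max(r)))
    return GeneticCorrelation(
        trait_pair=(t1, t2), component=component,
        mean=float(np.mean(r)), hpd_lower=lo, hpd_upper=hi, draws=r,
    )


def convergence_report(draws: PosteriorDraws, threshold: float = 0.1) -> pd.DataFrame:
    """Lag-1 autocorrelation and effective sample size per scalar parameter.

    The chain passes when every |lag-1 autocorrelation| is below the
    threshold (0.1, the mixing rule used for the production schedule).
    Constant chains are flagged degenerate and fail.
    """
    import arviz as az

    rows = []
    for name, x in draws.scalar_chains().items():
        if x.size < 2:
            raise ValueError("need >= 2 retained draws per parameter")
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            rows.append({"parameter": name, "lag1_autocorr": np.nan,
                         "ess": 0.0, "degenerate": True, "pass": False})
            continue
        ac1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        ess = float(az.ess(x[None, :]))
        rows.append({"parameter": name, "lag1_autocorr": ac1, "ess": ess,
                     "degenerate": False, "pass": abs(ac1) < threshold})
    rep = pd.DataFrame(rows)
    rep.attrs["pass"] = bool(rep["pass"].all())
    return rep


def component_regression_compare(
    draws: PosteriorDraws, response_trait: str, predictor_trait: str,
    mass: float = 0.95, var_floor: float = 1e-12,
) -> dict:
    """Posterior of the phylogenetic-minus-strain regression slope difference.

    Per draw, ``b_c = sigma_c:resp,pred / sigma2_c:pred`` for each component;
    the returned HPD of ``b_phylo - b_strain`` containing 0 is read as "the
    regression does not differ between the phylogenetic and strain
    components".  Draws where either predictor variance is numerically zero
    are skipped and counted.
    """
    traits = draws.traits
    r, p = traits.index(response_trait), traits.index(predictor_trait)
    Vp, Vs = draws.component("phylo"), draws.component("strain")
    ok = (Vp[:, p, p] > var_floor) & (Vs[:, p, p] > var_floor)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("skipped %d draw(s) with near-zero predictor variance", n_skip)
    b_p = Vp[ok, r, p] / Vp[ok, p, p]
    b_s = Vs[ok, r, p] / Vs[ok, p, p]
    diff = b_p - b_s
    lo, hi = hpd_interval(diff, mass)
    return {
        "mean": float(diff.mean()),
        "hpd_lower": lo,
        "hpd_upper": hi,
        "n_draws": int(diff.size),
        "n_skipped": n_skip,
        "b_phylo_mean": float(b_p.mean()),
        "b_strain_mean": float(b_s.mean()),
        "significant": not (lo <= 0.0 <= hi),
    }
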