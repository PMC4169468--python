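"""Mixed-effect Cox proportional-hazards models for the vial survival assay.

Flies are followed daily for 25 days after viral challenge; each vial of
~20 flies shares food, handling and stabbing, so the model puts a Gaussian
random effect (log-normal frailty) on each vial's log hazard on top of
fixed strain (and treatment) effects.  Deaths on the day after infection
are attributed to stabbing injury and excluded before fitting.

Estimation maximizes the Efron-tied partial likelihood penalized by the
Gaussian vial effects (penalty b'b / 2 sigma^2); the frailty variance is
optimized on a Laplace-approximate integrated likelihood, the approach of
the penalized-likelihood frailty literature.  Daily censuses produce heavy
ties, hence Efron as the default tie correction (Breslow available).

The per-vial protection trait fed to the comparative model is the negative
log hazard ratio versus the symbiont-free reference: ``-(beta_strain +
b_vial)``, so larger values mean better survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "exclude_day1_deaths",
    "fit_cox_mixed",
    "likelihood_ratio_test",
    "per_vial_protection",
    "strain_vs_control_tests",
    "cox_partial_loglik",
]

_COEF_DIVERGED = 10.0   # |log-HR| beyond this is treated as non-identified


@dataclass
class CoxFit:
    """A fitted (possibly mixed-effect) Cox proportional-hazards model."""

    fixed_effects: pd.Series            # log-hazard coefficients, reference = 0 (dropped)
    se: pd.Series                       # Wald standard errors
    frailty_variance: float             # vial random-effect variance (0 = fixed-only)
    vial_effects: pd.Series             # predicted random effects (empty if fixed-only)
    vial_strain: dict                   # vial -> strain for trait construction
    log_partial_likelihood: float       # Efron/Breslow partial log-likelihood at optimum
    integrated_loglik: float            # Laplace-integrated loglik (== partial if no frailty)
    n_events: int
    n_records: int
    fixed_terms: tuple[str, ...]
    ties: str = "efron"
    flags: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        """Log-likelihood used for model comparison."""
        return self.integrated_loglik

    def to_json_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects.to_dict(),
            "se": self.se.to_dict(),
            "frailty_variance": self.frailty_variance,
            "vial_effects": self.vial_effects.to_dict(),
            "log_partial_likelihood": self.log_partial_likelihood,
            "integrated_loglik": self.integrated_loglik,
            "n_events": self.n_events,
            "n_records": self.n_records,
            "fixed_terms": list(self.fixed_terms),
            "ties": self.ties,
            "flags": self.flags,
        }


def exclude_day1_deaths(records: pd.DataFrame) -> pd.DataFrame:
    """Drop deaths recorded on day 1 (stabbing-injury mortality).

    Censored day-1 records are retained; the number of removals is logged.
    """
    mask = (records["event"] == 1) & (records["day"] == 1)
    n = int(mask.sum())
    if n:
        logger.info("excluded %d day-1 death(s) attributed to stabbing injury", n)
    return records[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# partial likelihood machinery

def _design(records: pd.DataFrame, fixed_terms, reference: dict):
    """Dummy-coded fixed-effect design; reference levels dropped."""
    cols, names = [], []
    for term in fixed_terms:
        if ":" in term:
            f1, f2 = term.split(":")
            lv1 = [l for l in records[f1].unique() if l != reference.get(f1)]
            lv2 = [l for l in records[f2].unique() if l != reference.get(f2)]
            for a in lv1:
                for b in lv2:
                    cols.append(((records[f1] == a) & (records[f2] == b)).to_numpy(float))
                    names.append(f"{f1}[{a}]:{f2}[{b}]")
        else:
            for lv in records[term].unique():
                if lv == reference.get(term):
                    continue
                cols.append((records[term] == lv).to_numpy(float))
                names.append(f"{term}[{lv}]")
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return X, names


class _PartialLik:
    """Efron/Breslow partial likelihood, gradient and Hessian over a design W.

    Risk sets are indexed by the (few) distinct event days; per-day
    cross-products are accumulated once per evaluation, so cost is one
    ``W' diag(w) W`` pass regardless of the number of Newton iterations'
    risk-set structure.
    """

    def __init__(self, day: np.ndarray, event: np.ndarray, W: np.ndarray, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie correction {ties!r}")
        self.W = W
        self.ties = ties
        order = np.argsort(-day, kind="stable")   # descending day
        self.order = order
        self.day = day[order]
        self.event = event[order]
        self.Wo = W[order]
        self.n, self.p = W.shape
        # group boundaries over descending unique days
        self.udays, self.starts = np.unique(-self.day, return_index=True)
        self.udays = -self.udays
        self.event_days = np.unique(day[event == 1])
        if len(self.event_days) == 0:
            raise ValueError("no events in the data; cannot fit a Cox model")

    def loglik_grad_hess(self, theta: np.ndarray, need_hess: bool = True):
        eta = self.Wo @ theta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        Wo = self.Wo
        p = self.p
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p)) if need_hess else None

        # cumulative (over descending days) risk-set sums
        S_cum = 0.0
        Z_cum = np.zeros(p)
        Q_cum = np.zeros((p, p)) if need_hess else None
        bounds = list(self.starts) + [self.n]
        for g in range(len(self.udays)):
            day = self.udays[g]
            sl = slice(bounds[g], bounds[g + 1])
            wg = w[sl]
            Wg = Wo[sl]
            S_cum += wg.sum()
            Z_cum = Z_cum + Wg.T @ wg
            if need_hess:
                Q_cum = Q_cum + (Wg * wg[:, None]).T @ Wg
            ev = self.event[sl] == 1
            d = int(ev.sum())
            if d == 0:
                continue
            We = Wg[ev]
            we = wg[ev]
            ll += float(eta[sl][ev].sum())
            grad += We.sum(axis=0)
            S_D = we.sum()
            Z_D = We.T @ we
            if need_hess:
                Q_D = (We * we[:, None]).T @ We
            if self.ties == "breslow":
                frac = np.zeros(d)
            else:
                frac = np.arange(d) / d
            phi = S_cum - frac * S_D          # length d
            a = 1.0 / phi
            ll -= float(np.log(phi).sum())
            sa, sab = a.sum(), (a * frac).sum()
            grad -= sa * Z_cum - sab * Z_D
            if need_hess:
                a2, a2b, a2b2 = (a**2).sum(), (a**2 * frac).sum(), (a**2 * frac**2).sum()
                hess -= sa * Q_cum - sab * Q_D
                hess += (
                    a2 * np.outer(Z_cum, Z_cum)
                    - a2b * (np.outer(Z_cum, Z_D) + np.outer(Z_D, Z_cum))
                    + a2b2 * np.outer(Z_D, Z_D)
                )
        return ll, grad, hess


def cox_partial_loglik(records: pd.DataFrame, coefs: dict, fixed_terms=("strain",),
                       reference: dict | None = None, ties: str = "efron") -> float:
    """Evaluate the tied partial log-likelihood at given coefficients.

    Exposed so tests can check the fitted maximum against brute-force
    (grid-search) maximization and hand-computed risk-set products.
    """
    reference = reference or {}
    X, names = _design(records, fixed_terms, reference)
    pl = _PartialLik(records["day"].to_numpy(), records["event"].to_numpy(), X, ties)
    theta = np.array([coefs.get(n, 0.0) for n in names])
    ll, _, _ = pl.loglik_grad_hess(theta, need_hess=False)
    return ll


def _newton(pl: _PartialLik, penalty_diag: np.ndarray, theta0: np.ndarray,
            tol: float = 1e-9, max_iter: int = 50):
    """Maximize penalized partial likelihood; returns theta, ll_pen, H_pen."""
    theta = theta0.copy()

    def pen_ll(th):
        ll, g, H = pl.loglik_grad_hess(th)
        return (ll - 0.5 * float(penalty_diag @ th**2),
                g - penalty_diag * th,
                -H + np.diag(penalty_diag))

    f, g, H = pen_ll(theta)
    for _ in range(max_iter):
        Hj = H + 1e-10 * np.eye(len(theta))
        try:
            step = np.linalg.solve(Hj, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hj, g, rcond=None)[0]
        # step-halving line search
        for _ in range(30):
            new = theta + step
            fn, gn, Hn = pen_ll(new)
            if fn >= f - 1e-12:
                break
            step *= 0.5
        if not np.isfinite(fn):
            raise FloatingPointError("penalized partial likelihood diverged")
        converged = abs(fn - f) < tol * (abs(f) + 1.0)
        theta, f, g, H = new, fn, gn, Hn
        if converged:
            break
    return theta, f, H


def fit_cox_mixed(
    records: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("strain",),
    random: str | None = "vial",
    reference: dict | None = None,
    frailty_variance: float | None = None,
    ties: str = "efron",
    reference_strain: str = "w_free",
    max_outer_iter: int = 200,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model with an optional vial frailty.

    Parameters
    ----------
    records
        Long survival table with columns ``day``, ``event`` and every factor
        named in ``fixed_terms`` / ``random``.  Censoring at the end of
        follow-up must already be encoded as ``event = 0``.
    fixed_terms
        Factor names, with ``"a:b"`` for an interaction; reference levels
        (coefficient fixed at 0) come from ``reference`` and default to
        ``reference_strain`` for the ``strain`` factor.
    random
        Column defining the Gaussian random effect (one level per vial), or
        ``None`` for a fixed-effects-only fit.
    frailty_variance
        Fix the vial variance at this value instead of estimating it
        (0 reduces to the fixed-effects model but keeps vial predictions).

    The frailty variance is estimated by maximizing the Laplace-approximate
    integrated partial likelihood over log sigma^2 (bounded scalar search),
    with the penalized Newton fit warm-started between evaluations.
    """
    reference = dict(reference or {})
    reference.setdefault("strain", reference_strain)
    if (records["event"] == 1).sum() == 0:
        raise ValueError("no events in the data; cannot fit a Cox model")
    records = records.reset_index(drop=True)

    X, fixed_names = _design(records, fixed_terms, reference)
    p = X.shape[1]
    if random is not None:
        vials = list(dict.fromkeys(records[random]))
        q = len(vials)
        Z = np.zeros((len(records), q))
        vidx = {v: i for i, v in enumerate(vials)}
        Z[np.arange(len(records)), [vidx[v] for v in records[random]]] = 1.0
        W = np.hstack([X, Z])
    else:
        vials, q = [], 0
        W = X

    pl = _PartialLik(records["day"].to_numpy(), records["event"].to_numpy(), W, ties)
    theta_warm = np.zeros(p + q)

    def fit_at(sigma2: float):
        nonlocal theta_warm
        pen = np.zeros(p + q)
        if q:
            pen[p:] = 1.0 / max(sigma2, 1e-12)
        theta, f_pen, H_pen = _newton(pl, pen, theta_warm, tol=tol)
        theta_warm = theta
        return theta, f_pen, H_pen

    if q == 0 or (frailty_variance is not None and frailty_variance == 0.0):
        if q:  # variance fixed at zero: vial effects are exactly 0
            theta, f_pen, H_pen = fit_at(1e-12)
            theta[p:] = 0.0
        theta, f_pen, H_pen = (_newton(pl, np.zeros(p), np.zeros(p))
                               if q == 0 else (theta, f_pen, H_pen))
        sigma2_hat = 0.0
        ilik = f_pen if q == 0 else pl.loglik_grad_hess(theta)[0]
        ll_partial = ilik
        if q == 0:
            ll_partial = f_pen
            ilik = f_pen
    else:
        def neg_ilik(log_s2: float) -> float:
            s2 = float(np.exp(log_s2))
            theta, f_pen, H_pen = fit_at(s2)
            Hbb = H_pen[p:, p:]   # already includes I/s2
            sign, logdet = np.linalg.slogdet(Hbb)
            if sign <= 0:
                return np.inf
            return -(f_pen - 0.5 * q * np.log(s2) - 0.5 * logdet)

        if frailty_variance is not None:
            sigma2_hat = float(frailty_variance)
        else:
            res = optimize.minimize_scalar(
                neg_ilik, bounds=(np.log(1e-6), np.log(10.0)), method="bounded",
                options={"xatol": 1e-6, "maxiter": max_outer_iter},
            )
            sigma2_hat = float(np.exp(res.x))
            if sigma2_hat <= 2e-6:
                sigma2_hat = 0.0
                logger.info("frailty variance estimated at the zero boundary")
        theta, f_pen, H_pen = fit_at(max(sigma2_hat, 1e-12))
        Hbb = H_pen[p:, p:]
        sign, logdet = np.linalg.slogdet(Hbb)
        ilik = f_pen - 0.5 * q * np.log(max(sigma2_hat, 1e-12)) - 0.5 * logdet
        ll_partial = pl.loglik_grad_hess(theta, need_hess=False)[0]

    # Wald SEs from the inverse penalized Hessian (fixed-effect block)
    flags = []
    try:
        cov = np.linalg.inv(H_pen + 1e-12 * np.eye(p + q))
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    beta = theta[:p]
    for i, name in enumerate(fixed_names):
        if abs(beta[i]) > _COEF_DIVERGED:
            se[i] = np.inf
            flags.append(f"non-identified coefficient {name} (|log-HR| > {_COEF_DIVERGED})")
            logger.warning("coefficient %s appears non-identified; SE set to inf", name)

    vial_effects = pd.Series(theta[p:], index=vials, dtype=float)
    vial_strain = (
        records.drop_duplicates(random)[[random, "strain"]]
        .set_index(random)["strain"].to_dict()
        if random is not None and "strain" in records.columns else {}
    )
    return CoxFit(
        fixed_effects=pd.Series(beta, index=fixed_names, dtype=float),
        se=pd.Series(se, index=fixed_names, dtype=float),
        frailty_variance=float(sigma2_hat),
        vial_effects=vial_effects,
        vial_strain=vial_strain,
        log_partial_likelihood=float(ll_partial),
        integrated_loglik=float(ilik),
        n_events=int((records["event"] == 1).sum()),
        n_records=len(records),
        fixed_terms=tuple(fixed_terms),
        ties=ties,
        flags=flags,
    )


def likelihood_ratio_test(full: CoxFit, reduced: CoxFit) -> tuple[float, int, float]:
    """LRT of nested fixed-effect structures: returns (chi2, df, p)."""
    if full.n_records != reduced.n_records:
        raise ValueError("models were fitted to different records")
    if not set(reduced.fixed_effects.index) <= set(full.fixed_effects.index):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.fixed_effects) - len(reduced.fixed_effects)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -1e-6 * (abs(full.loglik) + 1):
            logger.warning("negative LRT statistic %.3g clipped to 0", chi2)
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def per_vial_protection(fit: CoxFit, reference_strain: str = "w_free") -> pd.DataFrame:
    """Per-vial protection traits: ``-(beta_strain + b_vial)``.

    The reference strain's coefficient is 0 by construction, so its vials
    get ``-b_vial``.  Larger values mean lower hazard (better survival).
    """
    if len(fit.vial_effects) == 0:
        raise ValueError("fit has no vial effects; refit with random='vial'")
    rows = []
    for vial, b in fit.vial_effects.items():
        strain = fit.vial_strain.get(vial)
        if strain is None:
            raise KeyError(f"vial {vial!r} has no strain attribution in the fit")
        name = f"strain[{strain}]"
        beta = 0.0 if strain == reference_strain else float(fit.fixed_effects.get(name, 0.0))
        rows.append({"vial": vial, "strain": strain, "value": -(beta + float(b))})
    return pd.DataFrame(rows)


def strain_vs_control_tests(fit: CoxFit) -> pd.DataFrame:
    """Per-strain Wald tests versus the reference (no multiplicity correction).

    Mirrors per-strain significance stars against the symbiont-free control;
    coefficients flagged non-identified report p = 1.
    """
    rows = []
    for name in fit.fixed_effects.index:
        if not name.startswith("strain[") or ":" in name:
            continue
        beta = fit.fixed_effects[name]
        se = fit.se[name]
        if not np.isfinite(se) or se == 0:
            rows.append({"strain": name[7:-1], "coef": beta, "se": se,
                         "z": np.nan, "p": 1.0, "flag": "non-identified"})
            continue
        z = beta / se
        rows.append({"strain": name[7:-1], "coef": beta, "se": se,
                     "z": z, "p": float(2 * stats.norm.sf(abs(z))), "flag": ""})
    return pd.DataFrame(rows)
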