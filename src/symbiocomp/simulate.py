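"""Synthetic data with known ground truth for every pipeline stage.

Emulates the design of a strain-panel protection experiment: ~19 symbiont
strains plus a symbiont-free control line, six replicate assay days with two
vials of twenty flies per strain per treatment (DCV, FHV or a Ringer's mock
infection, controls at double replication), a 25-day daily census with day-1
deaths attributed to stabbing injury, and qPCR plates of pooled flies (ten
pools of ten flies, two technical replicates) for symbiont density, viral
titer and host gene expression.

Strain-level trait effects are drawn as the sum of a phylogenetic component
(trait covariance ``V_p``, strain covariance the shared-ancestry matrix
``A``) and an independent strain component (trait covariance ``V_s``), the
additive decomposition the comparative model estimates.  All outputs are
deterministic given the seeds in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny, SharedAncestryMatrix, read_newick, shared_ancestry_matrix

__all__ = [
    "QpcrDesign",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_strain_effects",
    "simulate_survival",
    "simulate_qpcr",
    "simulate_dilution_series",
    "simulate_study",
]

TREATMENTS = ("DCV", "FHV", "Ringer")


@dataclass
class QpcrDesign:
    """Plate layout and noise model for the simulated qPCR assays."""

    n_pools: int = 10           # pools of flies per strain
    flies_per_pool: int = 10
    efficiency_target: float = 1.9   # amplification factor per cycle
    efficiency_ref: float = 2.0      # reference gene runs at 100% efficiency
    ct_noise_sd: float = 0.15        # additive Gaussian noise on Ct (cycles)
    n_plates: int = 4
    plate_shift_sd: float = 0.3      # shared Ct shift per 96-well plate
    tech_reps: int = 2
    base_ct_ref: float = 18.0        # reference-gene Ct before plate shift


@dataclass
class SimulationConfig:
    """Design constants of the simulated study.

    Defaults mirror the protection-panel design: 19 strains + 1 symbiont-free
    line, 2 vials/day x 6 days per strain x treatment, 20 flies per vial,
    25-day follow-up, daily census.  Hazards are per-day rates; strain and
    vial effects act multiplicatively on the hazard (additively on its log).
    """

    n_strains: int = 19
    tree_seed: int = 11
    data_seed: int = 12
    trait_names: tuple[str, ...] = ("protection_DCV", "protection_FHV")
    V_s: np.ndarray | None = None    # trait x trait strain covariance
    V_p: np.ndarray | None = None    # trait x trait phylogenetic covariance
    n_vials_per_strain_per_treatment: int = 12   # 2 vials/day x 6 days
    control_replication: int = 2     # symbiont-free line run at double replication
    flies_per_vial: int = 20
    follow_up_days: int = 25
    baseline_hazard: dict = field(
        default_factory=lambda: {"DCV": 0.10, "FHV": 0.08, "Ringer": 0.01}
    )
    vial_frailty_sd: float = 0.2
    day1_injury_death_rate: float = 0.03  # extra day-1 mortality from stabbing
    reference_strain: str = "w_free"
    qpcr: QpcrDesign = field(default_factory=QpcrDesign)

    def strain_labels(self) -> list[str]:
        return [f"wSim{i:02d}" for i in range(1, self.n_strains + 1)]

    def validate(self) -> None:
        for name, val in [
            ("n_strains", self.n_strains),
            ("n_vials_per_strain_per_treatment", self.n_vials_per_strain_per_treatment),
            ("flies_per_vial", self.flies_per_vial),
        ]:
            if val < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")
        if any(h <= 0 for h in self.baseline_hazard.values()):
            raise ValueError("baseline hazards must be positive")
        if self.vial_frailty_sd < 0 or self.qpcr.ct_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for E in (self.qpcr.efficiency_target, self.qpcr.efficiency_ref):
            if not (1.0 < E <= 2.2):
                raise ValueError(f"qPCR efficiency must be in (1, 2.2], got {E}")


@dataclass
class GroundTruth:
    """Generating values recorded for parameter-recovery tests."""

    trait_names: list[str]
    strains: list[str]
    phylo_component: pd.DataFrame     # strain x trait
    strain_component: pd.DataFrame    # strain x trait
    total: pd.DataFrame               # sum of the two components
    r_g_strain: np.ndarray            # trait x trait correlation implied by V_s
    r_g_phylo: np.ndarray | None
    neg_log_hazard_ratio: pd.DataFrame | None = None  # strain x treatment
    relative_quantity: pd.DataFrame | None = None     # strain x gene


def _corr(V: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(V))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = V / np.outer(d, d)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def simulate_tree(n_strains: int, seed: int) -> Phylogeny:
    """A random ultrametric tree from the standard Kingman coalescent.

    With *k* lineages the waiting time to the next merge is exponential with
    rate k(k-1)/2 (time in coalescent units); a uniformly chosen pair merges.
    """
    if n_strains < 2:
        raise ValueError(f"need >= 2 strains, got {n_strains}")
    rng = np.random.default_rng(seed)
    labels = [f"wSim{i:02d}" for i in range(1, n_strains + 1)]
    # (newick subtree string, height of subtree root)
    lineages: list[tuple[str, float]] = [(lab, 0.0) for lab in labels]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (si, hi), (sj, hj) = lineages[i], lineages[j]
        merged = (f"({si}:{t - hi:.10f},{sj}:{t - hj:.10f})", t)
        lineages = [lineages[m] for m in range(k) if m not in (i, j)] + [merged]
    return read_newick(lineages[0][0] + ";")


def simulate_strain_effects(
    tree: Phylogeny | None,
    V_s: np.ndarray,
    V_p: np.ndarray,
    seed: int,
    trait_names: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-strain trait vectors as phylogenetic + independent components.

    The phylogenetic component has covariance ``V_p (x) A`` (Kronecker:
    trait covariance ``V_p``, between-strain covariance the shared-ancestry
    matrix of ``tree``); the strain component is i.i.d. across strains with
    trait covariance ``V_s``.  Both components are recorded separately in
    the returned :class:`GroundTruth`.
    """
    V_s = np.atleast_2d(np.asarray(V_s, dtype=float))
    V_p = np.atleast_2d(np.asarray(V_p, dtype=float))
    if V_s.shape != V_p.shape:
        raise ValueError(f"V_s {V_s.shape} and V_p {V_p.shape} differ in trait dimension")
    T = V_s.shape[0]
    if trait_names is None:
        trait_names = [f"trait_{t+1}" for t in range(T)]
    if len(trait_names) != T:
        raise ValueError("trait_names length must match covariance dimension")

    if tree is not None:
        A = shared_ancestry_matrix(tree)
        labels, Amat = A.labels, A.A
    else:
        raise ValueError("a tree is required (use a star tree for no phylogenetic signal)")
    S = len(labels)

    rng = np.random.default_rng(seed)
    # matrix-normal draws: U = L_A Z L_V' has cov (V (x) A) in vec(strain-major)
    La = _psd_factor(Amat)
    phylo = La @ rng.standard_normal((S, T)) @ _psd_factor(V_p).T
    indep = rng.standard_normal((S, T)) @ _psd_factor(V_s).T

    phylo_df = pd.DataFrame(phylo, index=labels, columns=trait_names)
    strain_df = pd.DataFrame(indep, index=labels, columns=trait_names)
    truth = GroundTruth(
        trait_names=list(trait_names),
        strains=list(labels),
        phylo_component=phylo_df,
        strain_component=strain_df,
        total=phylo_df + strain_df,
        r_g_strain=_corr(V_s),
        r_g_phylo=_corr(V_p),
    )
    return truth.total.copy(), truth


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """A factor L with L L' = M for symmetric PSD M (eigen-based, jitter-free)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    w, Q = np.linalg.eigh(M)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("covariance matrix must be positive semi-definite")
    return Q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_survival(
    strain_log_hr: pd.DataFrame | dict,
    config: SimulationConfig,
    seed: int,
    treatments: tuple[str, ...] = TREATMENTS,
) -> pd.DataFrame:
    """Simulate the daily-census survival assay.

    ``strain_log_hr`` maps strain x treatment to the log hazard ratio versus
    the symbiont-free reference (which is implicitly 0).  Per fly, a
    continuous exponential event time under hazard
    ``baseline * exp(log_hr + vial_frailty)`` is discretized to whole days by
    ceiling (the census records deaths once per day); events beyond the
    follow-up window are censored at ``follow_up_days``.  An additional
    day-1 Bernoulli death (stabbing injury) exercises the day-1 exclusion
    rule downstream.

    Returns a long table: fly_id, strain, treatment, vial, day, event.
    """
    config.validate()
    if isinstance(strain_log_hr, dict):
        strain_log_hr = pd.DataFrame(strain_log_hr)
    rng = np.random.default_rng(seed)
    ref = config.reference_strain
    strains = [ref] + [s for s in strain_log_hr.index if s != ref]
    rows = []
    fly = 0
    for trt in treatments:
        lam0 = config.baseline_hazard[trt]
        for strain in strains:
            log_hr = 0.0 if strain == ref else float(strain_log_hr.loc[strain, trt])
            n_vials = config.n_vials_per_strain_per_treatment * (
                config.control_replication if strain == ref else 1
            )
            for v in range(n_vials):
                vial_id = f"{strain}.{trt}.v{v+1:02d}"
                frailty = rng.normal(0.0, config.vial_frailty_sd)
                lam = lam0 * np.exp(log_hr + frailty)
                times = rng.exponential(1.0 / lam, size=config.flies_per_vial)
                days = np.ceil(times).astype(int)
                injured = rng.random(config.flies_per_vial) < config.day1_injury_death_rate
                days = np.where(injured, 1, days)
                for d, inj in zip(days, injured):
                    fly += 1
                    if config.follow_up_days == 0 or (d > config.follow_up_days):
                        day, event = config.follow_up_days, 0
                        if config.follow_up_days == 0:
                            day = 0
                    else:
                        day, event = int(d), 1
                    rows.append((f"fly{fly:06d}", strain, trt, vial_id, day, event))
    return pd.DataFrame(
        rows, columns=["fly_id", "strain", "treatment", "vial", "day", "event"]
    )


def simulate_qpcr(
    true_relative_quantity: pd.Series | dict,
    config: SimulationConfig,
    seed: int,
    gene: str = "wsp",
    reference_gene: str = "actin5C",
) -> pd.DataFrame:
    """Simulate Ct tables for one target gene against its reference gene.

    ``true_relative_quantity`` gives the true target/reference abundance
    ratio per strain (> 0); each strain contributes ``n_pools`` pools, each
    measured in ``tech_reps`` technical replicates for both genes.  The
    reference-gene Ct is drawn around a plate-shifted baseline; the target
    Ct satisfies ``E_t^(-ct_t) = q * E_r^(-ct_r)`` before noise, so the
    Pfaffl quantification inverts the simulation exactly in the noiseless
    limit.  Plate shifts are shared by every well on a plate.

    Returns a long table: pool_id, strain, gene, plate, tech_rep, ct.
    """
    config.validate()
    q = pd.Series(true_relative_quantity, dtype=float)
    if (q <= 0).any():
        bad = list(q.index[q <= 0])
        raise ValueError(f"relative quantities must be positive; offending strains: {bad}")
    d = config.qpcr
    rng = np.random.default_rng(seed)
    plate_shift = rng.normal(0.0, d.plate_shift_sd, size=d.n_plates)
    rows = []
    pool_counter = 0
    lnEt, lnEr = np.log(d.efficiency_target), np.log(d.efficiency_ref)
    for strain, quant in q.items():
        for p in range(d.n_pools):
            pool_counter += 1
            pool_id = f"pool{pool_counter:04d}"
            plate = pool_counter % d.n_plates
            ct_ref_true = d.base_ct_ref + plate_shift[plate] + rng.normal(0.0, 0.5)
            # E_t^(-ct_t) = q * E_r^(-ct_r)  =>  ct_t = (ct_r*lnEr - ln q)/lnEt
            ct_tgt_true = (ct_ref_true * lnEr - np.log(quant)) / lnEt
            for r in range(d.tech_reps):
                rows.append((pool_id, strain, reference_gene, f"plate{plate+1}", r + 1,
                             ct_ref_true + rng.normal(0.0, d.ct_noise_sd)))
                rows.append((pool_id, strain, gene, f"plate{plate+1}", r + 1,
                             ct_tgt_true + rng.normal(0.0, d.ct_noise_sd)))
    return pd.DataFrame(
        rows, columns=["pool_id", "strain", "gene", "plate", "tech_rep", "ct"]
    )


def simulate_dilution_series(
    efficiency: float,
    seed: int | None = None,
    n_points: int = 5,
    dilution_step: float = 10.0,
    intercept_ct: float = 15.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Ct values over a serial dilution with slope ``-1/log10(E)``."""
    if not (1.0 < efficiency <= 2.2):
        raise ValueError(f"efficiency must be in (1, 2.2], got {efficiency}")
    rng = np.random.default_rng(seed)
    log10_input = -np.arange(n_points) * np.log10(dilution_step)
    slope = -1.0 / np.log10(efficiency)
    ct = intercept_ct + slope * log10_input
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"log10_input": log10_input, "ct": ct})


def simulate_study(config: SimulationConfig | None = None) -> dict:
    """Generate one full synthetic study: tree, effects, survival and qPCR.

    The protection traits drawn by :func:`simulate_strain_effects` are used
    as negative log hazard ratios (positive trait = protective = lower
    hazard); symbiont density is simulated as an additional correlated trait
    when present in ``trait_names`` (any trait not starting with
    ``protection_`` is treated as a log relative quantity for qPCR).
    """
    config = config or SimulationConfig()
    config.validate()
    T = len(config.trait_names)
    V_s = config.V_s if config.V_s is not None else 0.25 * np.eye(T)
    V_p = config.V_p if config.V_p is not None else np.zeros((T, T))
    tree = simulate_tree(config.n_strains, config.tree_seed)
    effects, truth = simulate_strain_effects(
        tree, V_s, V_p, config.data_seed, trait_names=list(config.trait_names)
    )
    ss = np.random.SeedSequence(config.data_seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    prot_traits = [t for t in config.trait_names if t.startswith("protection_")]
    log_hr = pd.DataFrame(0.0, index=effects.index, columns=list(TREATMENTS))
    for t in prot_traits:
        trt = t.split("_", 1)[1]
        log_hr[trt] = -effects[t]
    truth.neg_log_hazard_ratio = -log_hr
    surv = simulate_survival(log_hr, config, child[0])

    qpcr_tables = {}
    quant_traits = [t for t in config.trait_names if not t.startswith("protection_")]
    rq = {}
    for i, t in enumerate(quant_traits):
        quants = np.exp(effects[t])
        rq[t] = quants
        qpcr_tables[t] = simulate_qpcr(quants, config, child[1] + i, gene=t)
    if rq:
        truth.relative_quantity = pd.DataFrame(rq)

    return {
        "config": config,
        "tree": tree,
        "effects": effects,
        "truth": truth,
        "survival": surv,
        "qpcr": qpcr_tables,
    }
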