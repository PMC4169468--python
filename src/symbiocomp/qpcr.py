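"""Relative quantification of qPCR cycle-threshold (Ct) tables.

Turns raw Ct measurements into relative symbiont density, viral titer and
host gene expression traits: technical replicates are averaged on the Ct
scale, amplification-efficiency differences between target and reference
genes are handled by the Pfaffl method, and host-gene expression values are
normalized within 96-well plates (z-scored per plate per gene).

The central identity: a target amplifying with per-cycle efficiency ``E``
reaches threshold after ``ct`` cycles starting from an amount proportional
to ``E**(-ct)``.  The relative quantity of target vs reference is therefore

    ratio = E_target**(-ct_target) / E_ref**(-ct_ref)

which reduces to the textbook ``2**(ct_ref - ct_target)`` when both
efficiencies are the ideal doubling, ``E = 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EfficiencyEstimate",
    "QuantConfig",
    "average_technical_replicates",
    "relative_quantity",
    "estimate_efficiency_dilution",
    "efficiency_correct_ct",
    "plate_normalize",
    "quantify",
]

_E_RANGE = (1.0, 2.2)


def _check_efficiency(E: float, name: str = "E") -> None:
    if not (_E_RANGE[0] < E <= _E_RANGE[1]):
        raise ValueError(
            f"{name} = {E} outside the validated efficiency range ({_E_RANGE[0]}, {_E_RANGE[1]}]"
        )


@dataclass
class EfficiencyEstimate:
    """Amplification efficiency per cycle for one gene."""

    gene: str
    E: float
    source: str = "dilution series"   # or "within-experiment"
    slope: float | None = None
    r_squared: float | None = None


@dataclass
class QuantConfig:
    """Labels and switches for trait assembly from a Ct table.

    Reference genes are configuration, not hard-coded: density and host-gene
    expression are measured against a host housekeeping gene (actin 5C in
    the motivating design, with 100% efficiency so its Ct needs no
    correction), viral titers against a host mRNA control (EF1a100E).
    """

    reference_gene: str = "actin5C"
    efficiencies: dict = field(default_factory=dict)   # gene -> E; default 2.0
    average_scale: str = "ct"          # "ct" (convention) or "quantity"
    plate_normalize_traits: tuple[str, ...] = ()       # expression traits only
    exclude_strains: tuple[str, ...] = ()              # unstable transmitters
    discordance_ct: float = 1.0        # tech-rep spread that triggers a QC flag


def average_technical_replicates(
    measurements: pd.DataFrame,
    discordance_ct: float = 1.0,
    scale: str = "ct",
) -> pd.DataFrame:
    """Collapse technical replicates to one Ct per (pool, gene).

    Averaging is on the Ct scale by default (the dominant qPCR convention);
    ``scale="quantity"`` averages ``2**(-ct)`` instead and reports the
    equivalent Ct.  Pools whose replicate Cts spread more than
    ``discordance_ct`` cycles are flagged in the log but retained.
    """
    required = {"pool_id", "gene", "ct"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if not np.isfinite(measurements["ct"]).all() or (measurements["ct"] <= 0).any():
        raise ValueError("all Ct values must be finite and positive")

    keep = [c for c in ("strain", "plate") if c in measurements.columns]
    grouped = measurements.groupby(["pool_id", "gene"], sort=False)
    rows = []
    for (pool, gene), grp in grouped:
        spread = grp["ct"].max() - grp["ct"].min()
        if spread > discordance_ct:
            logger.warning(
                "discordant technical replicates for pool %s gene %s: "
                "Ct spread %.2f cycles", pool, gene, spread,
            )
        if scale == "ct":
            ct = grp["ct"].mean()
        elif scale == "quantity":
            ct = -np.log2(np.mean(2.0 ** (-grp["ct"])))
        else:
            raise ValueError(f"unknown averaging scale {scale!r}")
        rows.append({"pool_id": pool, "gene": gene, "ct": ct,
                     **{c: grp[c].iloc[0] for c in keep}})
    return pd.DataFrame(rows)


def relative_quantity(
    ct_target: float, ct_ref: float, E_target: float = 2.0, E_ref: float = 2.0
) -> float:
    """Efficiency-corrected target/reference abundance ratio (Pfaffl).

    ``E_ref**ct_ref / E_target**ct_target``; equals ``2**(ct_ref-ct_target)``
    at ideal efficiency on both genes.
    """
    _check_efficiency(E_target, "E_target")
    _check_efficiency(E_ref, "E_ref")
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return float(E_target ** (-ct_target) / E_ref ** (-ct_ref))


def estimate_efficiency_dilution(
    dilution_log10_input: np.ndarray, cts: np.ndarray, gene: str = ""
) -> EfficiencyEstimate:
    """Amplification efficiency from a serial-dilution standard curve.

    Least-squares slope of Ct against log10(input amount); ``E =
    10**(-1/slope)``.  A perfect doubling assay has slope -3.3219 and
    ``E = 2`` (100% efficiency).

    Requires >= 3 dilution points spanning >= 2 orders of magnitude and a
    strictly decreasing Ct-vs-input relation (slope < 0).
    """
    x = np.asarray(dilution_log10_input, dtype=float)
    y = np.asarray(cts, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {x.size}")
    if x.max() - x.min() < 2.0:
        raise ValueError("dilution series must span >= 2 orders of magnitude")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError(f"non-monotone dilution series: fitted slope {slope:.3g} >= 0")
    E = 10.0 ** (-1.0 / slope)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return EfficiencyEstimate(gene=gene, E=float(E), source="dilution series",
                              slope=float(slope), r_squared=float(r2))


def efficiency_correct_ct(ct: float, E: float) -> float:
    """Rescale a Ct onto the ideal-efficiency (E = 2) scale.

    ``corrected = ct * log2(E)`` so that ``2**(-corrected) = E**(-ct)``;
    the identity when E = 2.
    """
    _check_efficiency(E)
    return float(np.asarray(ct, dtype=float) * np.log2(E))


def plate_normalize(values: np.ndarray, plate_ids: np.ndarray) -> np.ndarray:
    """Z-score values within each 96-well plate.

    Each plate's values get mean 0 and (ddof=1) standard deviation 1,
    removing shared plate-level batch shifts and scale differences.
    """
    values = np.asarray(values, dtype=float)
    plate_ids = np.asarray(plate_ids)
    out = np.empty_like(values)
    for plate in np.unique(plate_ids):
        mask = plate_ids == plate
        if mask.sum() < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 values")
        sd = values[mask].std(ddof=1)
        if sd == 0:
            raise ValueError(f"plate {plate!r} has zero variance")
        out[mask] = (values[mask] - values[mask].mean()) / sd
    return out


def quantify(
    ct_table: pd.DataFrame,
    config: QuantConfig | None = None,
    trait_name: str | None = None,
) -> pd.DataFrame:
    """Full Ct-to-trait pipeline for one target gene per row group.

    Steps: drop excluded strains; average technical replicates; for each
    pool pair (target, reference) compute the Pfaffl ratio with the
    configured efficiencies; optionally z-score within plates (host-gene
    expression traits).  Pools lacking a reference-gene measurement are
    dropped with a logged warning.

    Returns a long trait table: pool_id, strain, trait, value, plate.
    """
    config = config or QuantConfig()
    tab = ct_table[~ct_table["strain"].isin(config.exclude_strains)].copy()
    averaged = average_technical_replicates(
        tab, discordance_ct=config.discordance_ct, scale=config.average_scale
    )
    genes = [g for g in averaged["gene"].unique() if g != config.reference_gene]
    ref = averaged[averaged["gene"] == config.reference_gene].set_index("pool_id")
    rows = []
    for gene in genes:
        E_t = config.efficiencies.get(gene, 2.0)
        E_r = config.efficiencies.get(config.reference_gene, 2.0)
        tgt = averaged[averaged["gene"] == gene]
        trait = trait_name or gene
        for _, rec in tgt.iterrows():
            if rec["pool_id"] not in ref.index:
                logger.warning(
                    "pool %s lacks reference gene %s; excluded",
                    rec["pool_id"], config.reference_gene,
                )
                continue
            r = ref.loc[rec["pool_id"]]
            value = relative_quantity(rec["ct"], r["ct"], E_t, E_r)
            rows.append({
                "pool_id": rec["pool_id"],
                "strain": rec.get("strain"),
                "trait": trait,
                "value": value,
                "plate": rec.get("plate"),
            })
    out = pd.DataFrame(rows)
    if len(out) and config.plate_normalize_traits:
        for trait in out["trait"].unique():
            if trait in config.plate_normalize_traits:
                mask = out["trait"] == trait
                out.loc[mask, "value"] = plate_normalize(
                    np.log(out.loc[mask, "value"].to_numpy()),
                    out.loc[mask, "plate"].to_numpy(),
                )
    return out
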