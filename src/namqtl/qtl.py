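"""QTL region grouping and donor-specific effect cumulation.

Significant SNPs are grouped greedily: the most significant unassigned
SNP becomes a region peak and collects every unassigned significant SNP
on its chromosome within half the window (default 26 cM, matching the
mean donor introgression length).  Within a region, each family's
cumulated effect is the sum of allele-substitution effects (2*alpha) of
exactly those member SNPs at which the family's donor carries a
non-recurrent allele — identity-by-state patterns therefore yield a
different cumulated effect per donor (an allelic series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QtlRegion",
    "group_regions",
    "family_polymorphism",
    "cumulate_donor_effects",
    "donor_effect_table",
]


@dataclass(frozen=True)
class QtlRegion:
    peak_snp: str
    chromosome: str
    peak_cm: float
    window_lo: float
    window_hi: float
    members: tuple[str, ...]

    def __post_init__(self):
        if self.peak_snp not in self.members:
            raise ValueError("peak SNP must be a region member")


def group_regions(gwas_results: pd.DataFrame, gmap, window_cm: float = 26.0) -> list[QtlRegion]:
    """Greedy peak-first grouping of significant SNPs into regions.

    Peak ties (equal p) break by larger |effect|, then snp_id.  Every
    significant SNP ends up in exactly one region.
    """
    sig = gwas_results[gwas_results["significant"]].copy()
    if sig.empty:
        raise ValueError("no significant SNPs to group")
    sig["chromosome"] = gmap.chromosome_of(sig["snp_id"]).to_numpy()
    sig["position_cm"] = gmap.positions(sig["snp_id"]).to_numpy()
    sig = sig.sort_values(
        by=["p_holm", "p_value", "effect", "snp_id"],
        ascending=[True, True, False, True],
        key=lambda s: s.abs() if s.name == "effect" else s,
        kind="stable",
    ).reset_index(drop=True)
    half = window_cm / 2.0
    unassigned = sig
    regions: list[QtlRegion] = []
    while not unassigned.empty:
        peak = unassigned.iloc[0]
        same = unassigned[
            (unassigned["chromosome"] == peak["chromosome"])
            & ((unassigned["position_cm"] - peak["position_cm"]).abs() <= half)
        ]
        regions.append(
            QtlRegion(
                peak_snp=peak["snp_id"],
                chromosome=peak["chromosome"],
                peak_cm=float(peak["position_cm"]),
                window_lo=float(peak["position_cm"] - half),
                window_hi=float(peak["position_cm"] + half),
                members=tuple(same["snp_id"]),
            )
        )
        unassigned = unassigned.drop(same.index)
    return regions


def family_polymorphism(genotypes: pd.DataFrame, families: pd.Series) -> pd.DataFrame:
    """Empirical families x SNPs polymorphism table from dosage data.

    A SNP counts as polymorphic in a family when its lines carry a wild
    allele there (any non-missing dosage > 0).
    """
    fam = families.reindex(genotypes.index)
    return genotypes.gt(0).groupby(fam.to_numpy()).any()


def cumulate_donor_effects(
    region: QtlRegion,
    gwas_results: pd.DataFrame,
    polymorphic: pd.DataFrame,
) -> pd.Series:
    """Per-family cumulated allele-substitution effect at one region.

    ``polymorphic`` is a families x SNPs boolean table (a simulated
    founder panel's table or :func:`family_polymorphism` output).  A
    family sums 2*alpha over exactly the member SNPs at which it is
    polymorphic; families polymorphic at none get 0.
    """
    eff = gwas_results.set_index("snp_id")["effect"]
    missing = [s for s in region.members if s not in eff.index]
    if missing:
        raise ValueError(f"region members without effect estimates: {missing}")
    members = [s for s in region.members if s in polymorphic.columns]
    mask = polymorphic[members].astype(float)
    out = mask @ eff.loc[members]
    out.name = "cumulated_effect"
    out.index.name = "family"
    return out


def donor_effect_table(
    regions: list[QtlRegion],
    gwas_results: pd.DataFrame,
    polymorphic: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format donor effect table over all regions (bar-chart ready)."""
    rows = []
    for reg in regions:
        eff = cumulate_donor_effects(reg, gwas_results, polymorphic)
        for fam, v in eff.items():
            rows.append(
                {
                    "peak_snp": reg.peak_snp,
                    "chromosome": reg.chromosome,
                    "peak_cm": reg.peak_cm,
                    "family": fam,
                    "cumulated_effect": float(v),
                    "n_members": len(reg.members),
                }
            )
    return pd.DataFrame(rows)
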