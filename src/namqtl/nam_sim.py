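"""Synthetic NAM population generator.

Simulates a nested association mapping design in which a panel of wild
donor accessions is each crossed to one shared recurrent (elite) parent,
backcrossed once and selfed three times by single seed descent (BC1S3).
Genotypes are wild-allele dosages (0/1/2) at mapped SNPs; meiosis uses a
Poisson crossover process on the centimorgan scale (Haldane, no
interference).  Ordinal phenotypes arise from a single simulated QTL with
a donor-specific allelic series plus year, genotype-by-year and residual
noise.

All randomness flows from a single seed; per-stage generators are spawned
deterministically so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "GeneticMap",
    "QtlSpec",
    "SimConfig",
    "FounderPanel",
    "SimDataset",
    "build_map",
    "simulate_founders",
    "simulate_meiosis",
    "simulate_population",
    "genetic_values",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: Default chromosome labels (barley-style).
CHROMOSOMES = tuple(f"{i}H" for i in range(1, 8))


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


class GeneticMap:
    """A genetic map: SNP identifiers with chromosome and cM position.

    Parameters
    ----------
    frame:
        DataFrame with columns ``snp_id``, ``chromosome``, ``position_cm``.
        SNP ids must be unique and positions non-negative.  Rows are sorted
        by (chromosome appearance order, position) on construction.
    """

    REQUIRED = ("snp_id", "chromosome", "position_cm")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        frame = frame[list(self.REQUIRED)].copy()
        frame["snp_id"] = frame["snp_id"].astype(str)
        frame["chromosome"] = frame["chromosome"].astype(str)
        frame["position_cm"] = frame["position_cm"].astype(float)
        if frame["snp_id"].duplicated().any():
            dups = frame.loc[frame["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id in map: {dups[:5]}")
        if (frame["position_cm"] < 0).any():
            raise ValueError("map positions must be >= 0 cM")
        # stable sort: keep first-appearance chromosome order
        order = {c: i for i, c in enumerate(dict.fromkeys(frame["chromosome"]))}
        frame = frame.sort_values(
            by=["chromosome", "position_cm"],
            key=lambda s: s.map(order) if s.name == "chromosome" else s,
            kind="stable",
        ).reset_index(drop=True)
        self.frame = frame
        self._pos = frame.set_index("snp_id")["position_cm"]
        self._chrom = frame.set_index("snp_id")["chromosome"]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.frame["snp_id"])

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chromosome"]))

    def positions(self, snps=None) -> pd.Series:
        """cM positions indexed by snp_id (optionally for a subset)."""
        return self._pos if snps is None else self._pos.loc[list(snps)]

    def chromosome_of(self, snps=None) -> pd.Series:
        return self._chrom if snps is None else self._chrom.loc[list(snps)]

    def per_chromosome(self):
        """Yield ``(chromosome, integer row indices)`` in map order."""
        for chrom in self.chromosomes:
            idx = np.flatnonzero(self.frame["chromosome"].to_numpy() == chrom)
            yield chrom, idx

    def nearest_snp(self, chromosome: str, position_cm: float) -> str:
        """Mapped SNP closest to a cM position on the given chromosome."""
        sub = self.frame[self.frame["chromosome"] == chromosome]
        if sub.empty:
            raise ValueError(f"no SNPs on chromosome {chromosome!r}")
        i = (sub["position_cm"] - position_cm).abs().idxmin()
        return sub.loc[i, "snp_id"]


@dataclass(frozen=True)
class QtlSpec:
    """Ground-truth QTL: location plus per-family homozygous effects.

    ``effects`` maps family id -> phenotype-score change for the
    homozygous wild genotype relative to the recurrent parent.  Families
    absent from the mapping (or with effect 0) are non-carriers.
    """

    chromosome: str = "4H"
    position_cm: float = 111.3
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for fam, eff in self.effects.items():
            if not np.isfinite(eff):
                raise SimConfigError(f"non-finite QTL effect for family {fam}")

    @property
    def carriers(self) -> list[str]:
        return [f for f, e in self.effects.items() if e != 0.0]

    def effect_of(self, family: str) -> float:
        return float(self.effects.get(family, 0.0))


def _default_qtl_effects() -> dict[str, float]:
    # Six carrier families with a graded allelic series; the strongest
    # donor adds 4.33 score units for the homozygous wild genotype.
    return {
        "F11": 4.33,
        "F10": 3.60,
        "F23": 3.20,
        "F03": 2.70,
        "F25": 2.20,
        "F12": 1.88,
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic NAM experiment."""

    n_families: int = 25
    lines_per_family: int = 57
    snps_per_chromosome: int = 100
    chromosome_lengths: dict[str, float] = field(
        default_factory=lambda: {c: 150.0 for c in CHROMOSOMES}
    )
    polymorphism_fraction: float | dict[str, float] = 0.5
    qtl: QtlSpec | None = field(default_factory=lambda: QtlSpec(effects=_default_qtl_effects()))
    n_years: int = 2
    n_replicates: int = 2
    sigma2_year: float = 0.02
    sigma2_gxy: float = 0.25
    sigma2_resid: float = 0.05
    qtl_window_cm: float = 26.0
    dominance: float = 0.0
    clip_scores: bool = False
    discretize_scores: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1 or self.lines_per_family < 1:
            raise SimConfigError("need at least one family and one line per family")
        if self.snps_per_chromosome < 1 or not self.chromosome_lengths:
            raise SimConfigError("need at least one SNP and one chromosome")
        if self.n_years < 1 or self.n_replicates < 1:
            raise SimConfigError("years and replicates must be >= 1")
        for name in ("sigma2_year", "sigma2_gxy", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.qtl is not None and self.qtl.chromosome not in self.chromosome_lengths:
            raise SimConfigError(
                f"QTL chromosome {self.qtl.chromosome!r} not in chromosome_lengths"
            )
        if self.qtl is not None:
            length = self.chromosome_lengths[self.qtl.chromosome]
            if not 0 <= self.qtl.position_cm <= length:
                raise SimConfigError("QTL position outside chromosome length")

    @property
    def family_ids(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_families)]

    def poly_fraction(self, family: str) -> float:
        if isinstance(self.polymorphism_fraction, dict):
            frac = self.polymorphism_fraction.get(family, 0.5)
        else:
            frac = self.polymorphism_fraction
        if not 0.0 <= frac <= 1.0:
            raise SimConfigError("polymorphism fraction must be in [0, 1]")
        return float(frac)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class FounderPanel:
    """Which SNPs segregate in which family, plus the simulated QTL truth.

    ``polymorphic`` is a boolean families x SNPs table: True where the
    family's donor carries a non-recurrent allele (the SNP segregates in
    that family's BC1S3 progeny).
    """

    polymorphic: pd.DataFrame
    qtl: QtlSpec | None = None

    def __post_init__(self):
        if self.polymorphic.index.duplicated().any():
            raise ValueError("duplicate family ids in founder panel")

    @property
    def families(self) -> pd.Index:
        return self.polymorphic.index

    def is_polymorphic(self, family: str, snps) -> pd.Series:
        return self.polymorphic.loc[family, list(snps)]


def build_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced SNPs along each configured chromosome."""
    rows = []
    for chrom, length in config.chromosome_lengths.items():
        pos = np.linspace(0.0, float(length), config.snps_per_chromosome)
        for j, p in enumerate(pos):
            rows.append((f"{chrom}_{j + 1:04d}", chrom, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_cm"]))


def simulate_founders(
    config: SimConfig,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | None = None,
) -> FounderPanel:
    """Draw per-family polymorphism patterns over the map.

    Outside the QTL window each SNP is polymorphic in a family with the
    configured fraction, independently.  Inside the window (centered on
    the QTL, width ``qtl_window_cm``) the donors carry structured
    identity-by-state patterns: every carrier family is polymorphic at
    the QTL-flanking SNPs, the remaining window SNPs are each private to
    one carrier (shuffled assignment), and non-carrier donors share the
    recurrent-like haplotype there (no window polymorphism).  This makes
    the locus detectable in every carrier and gives each donor a
    distinguishable marker signature, so donor-specific cumulated
    effects can separate the allelic series.
    """
    gmap = build_map(config) if gmap is None else gmap
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fams = config.family_ids
    n_snp = len(gmap)
    poly = np.zeros((len(fams), n_snp), dtype=bool)
    for i, fam in enumerate(fams):
        poly[i] = rng.random(n_snp) < config.poly_fraction(fam)
    table = pd.DataFrame(poly, index=pd.Index(fams, name="family"), columns=gmap.snp_ids)
    if config.qtl is not None:
        q = config.qtl
        carriers = [f for f in q.carriers if f in table.index]
        on_chr = gmap.frame["chromosome"] == q.chromosome
        in_win = on_chr & (
            (gmap.frame["position_cm"] - q.position_cm).abs() <= config.qtl_window_cm / 2.0
        )
        window = list(gmap.frame.loc[in_win, "snp_id"])
        flank = _flanking_snps(gmap, q.chromosome, q.position_cm)
        non_carriers = [f for f in fams if f not in carriers]
        table.loc[non_carriers, window] = False
        if carriers:
            table.loc[carriers, flank] = True
            private = [s for s in window if s not in flank]
            owners = rng.permutation(len(private)) % len(carriers)
            for s, o in zip(private, owners):
                table.loc[carriers, s] = False
                table.loc[carriers[int(o)], s] = True
    return FounderPanel(polymorphic=table, qtl=config.qtl)


def _flanking_snps(gmap: GeneticMap, chromosome: str, position_cm: float) -> list[str]:
    sub = gmap.frame[gmap.frame["chromosome"] == chromosome]
    if sub.empty:
        raise ValueError(f"no SNPs on chromosome {chromosome!r}")
    below = sub[sub["position_cm"] <= position_cm].tail(1)
    above = sub[sub["position_cm"] >= position_cm].head(1)
    return list(dict.fromkeys(pd.concat([below, above])["snp_id"]))


# ---------------------------------------------------------------------------
# Meiosis

def _gamete_batch(h1: np.ndarray, h2: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """One gamete per row from stacked parental haplotype pairs.

    ``h1``/``h2`` are (n_lineages, n_snps) wild-allele indicator arrays in
    map order.  Crossovers follow a Poisson process on the cM scale with
    rate 1 per 100 cM (Haldane, no interference); the starting strand at
    the left chromosome end is chosen uniformly.
    """
    h1 = np.atleast_2d(np.asarray(h1))
    h2 = np.atleast_2d(np.asarray(h2))
    if h1.shape != h2.shape:
        raise ValueError("haplotype pair shapes differ")
    if h1.shape[1] != len(gmap):
        raise ValueError("haplotype length does not match the map")
    n = h1.shape[0]
    gamete = np.empty_like(h1)
    for _, idx in gmap.per_chromosome():
        pos = gmap.frame["position_cm"].to_numpy()[idx]
        lo, hi = pos[0], pos[-1]
        span = hi - lo
        counts = rng.poisson(span / 100.0, size=n)
        starts = rng.integers(0, 2, size=n)
        kmax = int(counts.max()) if n else 0
        if kmax == 0 or span == 0.0:
            parity = np.broadcast_to(starts[:, None], (n, idx.size))
        else:
            pts = rng.uniform(lo, hi, size=(n, kmax))
            live = np.arange(kmax)[None, :] < counts[:, None]
            pts = np.where(live, pts, np.inf)
            # crossovers strictly left of each marker flip the strand
            crossed = (pts[:, :, None] < pos[None, None, :]).sum(axis=1)
            parity = (starts[:, None] + crossed) % 2
        gamete[:, idx] = np.where(parity == 0, h1[:, idx], h2[:, idx])
    return gamete


def simulate_meiosis(
    haplotype_pair: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single gamete from one haplotype pair (mosaic of the two inputs)."""
    h1, h2 = haplotype_pair
    return _gamete_batch(np.asarray(h1)[None, :], np.asarray(h2)[None, :], gmap, rng)[0]


def simulate_population(
    founders: FounderPanel,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """BC1S3 genotypes for every line of every family.

    Descent per line: F1 (donor x recurrent) backcrossed to the recurrent
    parent, then three selfing generations carrying a single offspring
    forward (single seed descent).  Returns a lines x SNPs wild-allele
    dosage matrix (int8, values 0/1/2) and a line -> family Series.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if not founders.polymorphic.columns.equals(gmap.snp_ids):
        raise ValueError("founder panel SNPs do not match the map")
    blocks, fam_of = [], {}
    n = config.lines_per_family
    for fam in founders.families:
        donor = founders.polymorphic.loc[fam].to_numpy().astype(np.int8)
        zeros = np.zeros((n, len(gmap)), dtype=np.int8)
        donor_rep = np.broadcast_to(donor, (n, len(gmap)))
        # BC1: gamete from the F1 (donor/recurrent) + recurrent gamete
        hap_a = _gamete_batch(donor_rep, zeros, gmap, rng)
        hap_b = zeros.copy()
        for _ in range(3):  # S1..S3, single seed descent
            new_a = _gamete_batch(hap_a, hap_b, gmap, rng)
            new_b = _gamete_batch(hap_a, hap_b, gmap, rng)
            hap_a, hap_b = new_a, new_b
        dosage = (hap_a + hap_b).astype(np.int8)
        lines = [f"{fam}_{i + 1:03d}" for i in range(n)]
        blocks.append(pd.DataFrame(dosage, index=lines, columns=gmap.snp_ids))
        fam_of.update({ln: fam for ln in lines})
    genotypes = pd.concat(blocks)
    genotypes.index.name = "line"
    families = pd.Series(fam_of, name="family")
    families.index.name = "line"
    return genotypes, families.loc[genotypes.index]


# ---------------------------------------------------------------------------
# Phenotypes

def genetic_values(
    genotypes: pd.DataFrame,
    families: pd.Series,
    qtl: QtlSpec | None,
    gmap: GeneticMap,
    dominance: float = 0.0,
) -> pd.Series:
    """Deterministic genetic value of each line (baseline score 1).

    Additive by default: value = 1 + (dosage / 2) * family effect at the
    SNP nearest the QTL.  ``dominance`` in [0, 1] moves the heterozygote
    from midway (0) to the homozygous-wild value (1).
    """
    g = pd.Series(1.0, index=genotypes.index, name="genetic_value")
    if qtl is None:
        return g
    causal = gmap.nearest_snp(qtl.chromosome, qtl.position_cm)
    if causal not in genotypes.columns:
        raise ValueError(f"causal SNP {causal!r} missing from genotypes")
    dosage = genotypes[causal].astype(float)
    if dosage.isna().any():
        raise ValueError("lines with missing dosage at the QTL-linked SNP")
    x = dosage / 2.0 + dominance * (dosage == 1) / 2.0
    eff = families.map(qtl.effect_of).astype(float)
    return g + x * eff


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    families: pd.Series,
    config: SimConfig,
    gmap: GeneticMap,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plot-level scores: genetic value + year + GxY + residual noise.

    Returns long-format records (line, year, replicate, score).  Scores
    are continuous by default; ``clip_scores`` bounds them to [1, 7] and
    ``discretize_scores`` snaps them to the ordinal levels {1, 3, 5, 7}.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    g = genetic_values(genotypes, families, config.qtl, gmap, config.dominance)
    n_lines = len(g)
    years = [f"Y{t + 1}" for t in range(config.n_years)]
    reps = [f"R{k + 1}" for k in range(config.n_replicates)]
    year_eff = rng.normal(0.0, np.sqrt(config.sigma2_year), size=len(years))
    gxy = rng.normal(0.0, np.sqrt(config.sigma2_gxy), size=(n_lines, len(years)))
    rows = []
    for t, year in enumerate(years):
        base = g.to_numpy() + year_eff[t] + gxy[:, t]
        for rep in reps:
            resid = rng.normal(0.0, np.sqrt(config.sigma2_resid), size=n_lines)
            score = base + resid
            if config.clip_scores:
                score = np.clip(score, 1.0, 7.0)
            if config.discretize_scores:
                score = np.clip(2.0 * np.round((score - 1.0) / 2.0) + 1.0, 1.0, 7.0)
            rows.append(
                pd.DataFrame(
                    {"line": g.index, "year": year, "replicate": rep, "score": score}
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclass
class SimDataset:
    """Everything one simulated experiment produces, plus its truth."""

    config: SimConfig
    gmap: GeneticMap
    founders: FounderPanel
    genotypes: pd.DataFrame
    families: pd.Series
    phenotypes: pd.DataFrame
    genetic_values: pd.Series

    @property
    def causal_snp(self) -> str | None:
        q = self.config.qtl
        return None if q is None else self.gmap.nearest_snp(q.chromosome, q.position_cm)

    def plugin_heritability(self) -> float:
        """h2 implied by the realized genetic variance and noise settings."""
        c = self.config
        s2g = float(np.var(self.genetic_values.to_numpy(), ddof=1))
        denom = s2g + c.sigma2_gxy / c.n_years + c.sigma2_resid / (c.n_years * c.n_replicates)
        return s2g / denom


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: founders -> population -> phenotypes."""
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    gmap = build_map(config)
    founders = simulate_founders(config, gmap, np.random.default_rng(seqs[0]))
    genotypes, families = simulate_population(
        founders, gmap, config, np.random.default_rng(seqs[1])
    )
    phenotypes = simulate_phenotypes(
        genotypes, families, config, gmap, np.random.default_rng(seqs[2])
    )
    gvals = genetic_values(genotypes, families, config.qtl, gmap, config.dominance)
    return SimDataset(config, gmap, founders, genotypes, families, phenotypes, gvals)
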