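"""Cross-validated prediction ability of the marker model.

Repeatedly splits the lines into training (default 80%, drawn within
each family) and validation sets, reruns the whole association pipeline
on the training lines only — cofactor selection, scan, Holm adjustment —
and predicts the held-out BLUEs from the training-significant SNPs.  The
squared Pearson correlation between observed and predicted validation
BLUEs is recorded per run; the mean over runs is the prediction ability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas

__all__ = ["CvConfig", "CvReport", "cross_validate"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvConfig:
    n_runs: int = 100
    train_fraction: float = 0.8
    stratify_by_family: bool = True
    prediction: str = "joint"  # "joint" refit or "sum" of scan effects
    strict_kfold: bool = False
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.prediction not in ("joint", "sum"):
            raise ValueError("prediction must be 'joint' or 'sum'")


@dataclass
class CvReport:
    runs: np.ndarray
    run_seeds: list[int]
    n_significant: np.ndarray

    @property
    def mean_r2_val(self) -> float:
        return float(np.mean(self.runs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(len(self.runs)),
                "seed": self.run_seeds,
                "n_significant": self.n_significant,
                "r2_val": self.runs,
            }
        )


def _run_rng(master_seed: int, run: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, run)))


def _splits(families: pd.Series, config: CvConfig, run: int):
    """Training-line index sets for one run (one set, or 5 in k-fold mode)."""
    rng = _run_rng(config.seed, run)
    groups = (
        families.groupby(families).groups.items()
        if config.stratify_by_family
        else [("all", families.index)]
    )
    if config.strict_kfold:
        folds = [[] for _ in range(5)]
        for _, lines in groups:
            lines = np.asarray(list(lines))
            rng.shuffle(lines)
            for i, ln in enumerate(lines):
                folds[i % 5].append(ln)
        all_lines = set(families.index)
        return [sorted(all_lines - set(f)) for f in folds]
    train = []
    for _, lines in groups:
        lines = np.asarray(list(lines))
        n_train = max(1, int(round(config.train_fraction * len(lines))))
        train.extend(rng.choice(lines, size=min(n_train, len(lines)), replace=False))
    return [sorted(train)]


def _predict(G_train, y_train, G_val, sig_snps, scan_res, mode):
    if mode == "sum":
        eff = scan_res.set_index("snp_id").loc[sig_snps, "alpha"].to_numpy()
        fitted = G_train[sig_snps].to_numpy(dtype=float) @ eff
        intercept = float(y_train.mean() - fitted.mean())
        return G_val[sig_snps].to_numpy(dtype=float) @ eff + intercept
    X = np.hstack(
        [np.ones((len(y_train), 1)), G_train[sig_snps].to_numpy(dtype=float)]
    )
    beta, *_ = np.linalg.lstsq(X, y_train.to_numpy(), rcond=None)
    Xv = np.hstack([np.ones((len(G_val), 1)), G_val[sig_snps].to_numpy(dtype=float)])
    return Xv @ beta


def cross_validate(
    genotypes: pd.DataFrame,
    blues: pd.Series,
    families: pd.Series,
    config: CvConfig | None = None,
) -> CvReport:
    """Prediction ability R²_val over repeated stratified resampling.

    Genotypes must be complete (imputed).  Runs in which the training
    scan yields no significant SNP, or the predictions are constant,
    score 0 with a logged warning.
    """
    config = config or CvConfig()
    common = genotypes.index.intersection(blues.index)
    genotypes = genotypes.loc[common]
    blues = blues.loc[common].astype(float)
    families = families.reindex(common)
    sizes = families.value_counts()
    if (sizes < 5).any():
        small = sizes[sizes < 5].index.tolist()
        raise ValueError(f"families with fewer than 5 lines cannot be split 80/20: {small}")

    values, seeds, n_sig = [], [], []
    run = 0
    while len(values) < config.n_runs:
        for train_lines in _splits(families, config, run):
            if len(values) >= config.n_runs:
                break
            val_lines = sorted(set(common) - set(train_lines))
            G_tr, y_tr = genotypes.loc[train_lines], blues.loc[train_lines]
            G_va, y_va = genotypes.loc[val_lines], blues.loc[val_lines]

            cof = gwas.select_cofactors(G_tr, y_tr)
            res = gwas.scan(G_tr, y_tr, cof, alpha_level=config.alpha_level)
            sig = res.loc[res["significant"], "snp_id"].tolist()
            n_sig.append(len(sig))
            seeds.append(run)
            if not sig:
                log.warning("run %d: no significant SNP in training; r2_val = 0", run)
                values.append(0.0)
                continue
            pred = _predict(G_tr, y_tr, G_va, sig, res, config.prediction)
            obs = y_va.to_numpy()
            if np.ptp(pred) == 0 or np.ptp(obs) == 0:
                log.warning("run %d: constant observed/predicted values; r2_val = 0", run)
                values.append(0.0)
                continue
            r = float(np.corrcoef(obs, pred)[0, 1])
            values.append(r * r)
        run += 1
    return CvReport(
        runs=np.asarray(values), run_seeds=seeds, n_significant=np.asarray(n_sig)
    )
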